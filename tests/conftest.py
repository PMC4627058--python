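import numpy as np
import pytest

from utrscape.annotation import annotate_transcripts
from utrscape.synthetic import ExpressionModel, GroupSpec, simulate_transcriptome


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderate two-group synthetic transcriptome shared across tests:
    an AU-rich, ARE/uORF-rich olfr-like group against a control group."""
    specs = [
        GroupSpec(
            name="olfr",
            n_genes=40,
            utr5_len_dist=(200.0, 0.4),
            utr3_len_dist=(900.0, 0.4),
            au_frac_utr5=0.60,
            au_frac_utr3=0.60,
            are_rate_per_kb=10.0,
            uorf_lambda=1.1,
            nmd_arch_frac=0.1,
            expr_model=ExpressionModel(1.0, {"are_density": 0.04}, 0.3),
        ),
        GroupSpec(
            name="ctrl",
            n_genes=40,
            utr5_len_dist=(220.0, 0.4),
            utr3_len_dist=(1600.0, 0.4),
            au_frac_utr5=0.40,
            au_frac_utr3=0.45,
            are_rate_per_kb=5.0,
            uorf_lambda=0.5,
            nmd_arch_frac=0.05,
            expr_model=ExpressionModel(1.0, {}, 0.3),
        ),
    ]
    return simulate_transcriptome(specs, seed=20240917)


@pytest.fixture(scope="session")
def sim_annotated(sim_dataset):
    return annotate_transcripts(
        sim_dataset.models, sim_dataset.genome, sim_dataset.cds
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n, au=0.5):
    bases = np.array(list("ACGT"))
    p = [au / 2, (1 - au) / 2, (1 - au) / 2, au / 2]
    return "".join(bases[rng.choice(4, size=n, p=p)])
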