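"""Generator ground truth: round-trips, planted counts, distributions."""

import numpy as np
import pytest

from utrscape.annotation import annotate_transcripts
from utrscape.composition import composition
from utrscape.motifs import scan_are
from utrscape.orfs import find_uorfs
from utrscape.synthetic import (
    ExpressionModel,
    GroupSpec,
    erase_motif,
    plant_expression,
    plant_motif,
    simulate_transcriptome,
)


def simple_spec(**overrides):
    base = dict(
        name="grp",
        n_genes=5,
        utr5_len_dist=(150.0, 0.3),
        utr3_len_dist=(500.0, 0.3),
        au_frac_utr5=0.55,
        au_frac_utr3=0.55,
    )
    base.update(overrides)
    return GroupSpec(**base)


class TestSpecValidation:
    def test_rejects_bad_fractions_lengths_and_cds(self):
        with pytest.raises(ValueError):
            simple_spec(au_frac_utr3=1.2)
        with pytest.raises(ValueError):
            simple_spec(cds_len=935)
        with pytest.raises(ValueError):
            simple_spec(utr3_len_dist=(0.0, 0.5))

    def test_rejects_uorf_planting_in_tiny_utr5(self):
        with pytest.raises(ValueError, match="invalid spec"):
            simple_spec(utr5_len_dist=(20.0, 0.3), uorf_lambda=1.0)

    def test_empty_spec_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_transcriptome([], seed=1)


class TestPlantingPrimitives:
    def test_erase_motif_removes_all_occurrences(self):
        seq = "ATTTATTTACCATTTA"
        out = erase_motif(seq, "ATTTA", 2, "A")
        assert "ATTTA" not in out and len(out) == len(seq)

    def test_plant_motif_exact_and_crowding_error(self, rng):
        seq = "G" * 100
        out, offsets = plant_motif(seq, "ATTTA", 5, rng)
        assert [out[o : o + 5] for o in offsets] == ["ATTTA"] * 5
        with pytest.raises(ValueError):
            plant_motif("G" * 10, "ATTTA", 3, rng)


class TestGroundTruth:
    def test_single_transcript_round_trip(self):
        ds = simulate_transcriptome([simple_spec(n_genes=1)], seed=1)
        assert len(ds.models) == 1
        (tx,) = annotate_transcripts(ds.models, ds.genome, ds.cds)
        truth = ds.truth[0]
        assert tx.complete and not tx.excluded
        assert tx.cds_span == truth.cds_span
        assert tx.junctions == truth.junctions
        assert len(tx.utr5_seq) == truth.utr5_span[1]

    def test_truth_matches_rescan_across_seeds(self):
        spec = simple_spec(
            n_genes=25, are_rate_per_kb=8.0, uorf_lambda=1.2, nmd_arch_frac=0.15
        )
        for seed in (1, 2, 3):
            ds = simulate_transcriptome([spec], seed=seed)
            ann = annotate_transcripts(ds.models, ds.genome, ds.cds)
            for tx, truth in zip(ann, ds.truth):
                pent = [h for h in scan_are(tx.utr3_seq) if h.motif_id == "AUUUA"]
                assert len(pent) == truth.planted_pentamers == truth.are_pentamer_count
                uorfs = find_uorfs(tx.spliced_seq, tx.cds_span)
                assert len(uorfs) == len(truth.planted_uorf_starts) == truth.n_uorfs
                assert {u.start for u in uorfs} == set(truth.planted_uorf_starts)
                assert truth.nmd_flag == truth.planted_nmd

    def test_every_transcript_has_cds_intron_and_both_utrs(self, sim_dataset, sim_annotated):
        for tx, truth in zip(sim_annotated, sim_dataset.truth):
            assert tx.complete and not tx.excluded
            cds_start, cds_end = truth.cds_span
            assert any(cds_start < j < cds_end for j in truth.junctions)
            assert truth.utr5_span[1] >= 30 and len(tx.utr3_seq) >= 30

    def test_half_of_genes_on_minus_strand(self, sim_dataset):
        frac = np.mean([m.strand == "-" for m in sim_dataset.models])
        assert 0.3 < frac < 0.7

    def test_au_fraction_within_two_points_of_spec(self):
        spec = simple_spec(
            n_genes=200,
            au_frac_utr5=0.60,
            au_frac_utr3=0.60,
            are_rate_per_kb=10.0,
            utr3_len_dist=(1000.0, 0.5),
        )
        ds = simulate_transcriptome([spec], seed=11)
        ann = annotate_transcripts(ds.models, ds.genome, ds.cds)
        au5 = np.mean([composition(t.utr5_seq).au_frac for t in ann])
        au3 = np.mean([composition(t.utr3_seq).au_frac for t in ann])
        assert abs(au5 - 0.60) < 0.02
        assert abs(au3 - 0.60) < 0.02

    def test_planted_density_recovered(self):
        spec = simple_spec(n_genes=200, are_rate_per_kb=10.0, utr3_len_dist=(1000.0, 0.5))
        ds = simulate_transcriptome([spec], seed=5)
        dens = [t.features["are_density"] for t in ds.truth]
        se = np.std(dens) / np.sqrt(len(dens))
        assert abs(np.mean(dens) - 10.0) < 3 * se + 0.2


class TestPlantedExpression:
    def test_zero_betas_zero_noise_gives_baseline(self):
        ds = simulate_transcriptome(
            [simple_spec(n_genes=10, expr_model=ExpressionModel(2.0, {}, 0.0))],
            seed=3,
        )
        assert np.allclose(ds.expression["fpkm"], 100.0)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ExpressionModel(1.0, {"not_a_feature": 1.0}, 0.1)

    def test_deterministic_under_seed(self, sim_dataset):
        models = {"olfr": ExpressionModel(1.0, {"are_density": 0.05}, 0.3),
                  "ctrl": ExpressionModel(1.0, {}, 0.3)}
        a = plant_expression(sim_dataset.truth, models, seed=77)
        b = plant_expression(sim_dataset.truth, models, seed=77)
        assert (a["fpkm"] == b["fpkm"]).all()

    def test_positive_are_effect_recovered_by_regression(self):
        from utrscape.stats import build_feature_table, regress_expression

        spec = simple_spec(
            n_genes=300,
            are_rate_per_kb=8.0,
            utr3_len_dist=(800.0, 0.5),
            expr_model=ExpressionModel(1.0, {"are_density": 0.05}, 0.3),
        )
        ds = simulate_transcriptome([spec], seed=9)
        ann = annotate_transcripts(ds.models, ds.genome, ds.cds)
        table = build_feature_table(ann, expression=ds.expression)
        res = regress_expression(table, "are_pentamer_density")
        assert res.slope > 0 and res.p_value < 0.01

    def test_negative_gc_effect_recovered_by_regression(self):
        from utrscape.stats import build_feature_table, regress_expression

        spec = simple_spec(
            n_genes=300,
            expr_model=ExpressionModel(1.0, {"gc_utr5": -4.0}, 0.3),
        )
        ds = simulate_transcriptome([spec], seed=10)
        ann = annotate_transcripts(ds.models, ds.genome, ds.cds)
        table = build_feature_table(ann, expression=ds.expression)
        res = regress_expression(table, "gc_utr5")
        assert res.slope < 0 and res.p_value < 0.01


class TestArtifacts:
    def test_written_files_round_trip(self, tmp_path, sim_dataset):
        from utrscape import io as uio

        paths = sim_dataset.write(tmp_path)
        genome = uio.load_genome(paths["genome"])
        assert genome == sim_dataset.genome
        expr = uio.read_expression(paths["expression"])
        models = uio.read_transcript_models(
            paths["gtf"], expression=dict(zip(expr["gene_id"], expr["fpkm"]))
        )
        by_id = {m.transcript_id: m for m in models}
        for m in sim_dataset.models:
            got = by_id[m.transcript_id]
            assert got.exons == m.exons
            assert got.strand == m.strand
            assert got.group == m.group
            assert got.expression == pytest.approx(m.expression)
        cds = uio.read_cds_fasta(paths["cds"])
        assert cds == sim_dataset.cds
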