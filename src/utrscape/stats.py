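"""Feature-table assembly and group/expression statistics.

The feature table is the substrate of every figure-style analysis: one
row per complete, UTR-bearing transcript with lengths, composition, ARE
and miRNA site counts/densities, uORF burden, NMD architecture, optional
fold score, and expression. Group contrasts use pairwise Mann-Whitney U
by default (Welch t-test by flag); expression relationships are ordinary
least squares of log10(FPKM) on a feature, by default on one
max-expression transcript per gene to avoid pseudo-replicating gene-level
FPKM across isoforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import AnnotatedTranscript
from .composition import composition
from .motifs import scan_are, scan_mirna_sites
from .orfs import classify_nmd, find_uorfs


@dataclass(frozen=True)
class RegressionResult:
    x_name: str
    y_name: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    test_name: str
    groups: tuple[str, ...]
    summary: pd.DataFrame  # per-group n, mean, median, q1, q3
    pairwise: pd.DataFrame  # group_a, group_b, p_value, stars


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def build_feature_table(
    annotated: Iterable[AnnotatedTranscript],
    expression: pd.DataFrame | None = None,
    mirnas: Mapping[str, str] | None = None,
    fold_scores: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One row per complete, UTR-bearing transcript.

    ``expression`` is a gene-level (gene_id, fpkm) table; transcripts
    inherit their gene's FPKM. Transcripts with no expression record are
    dropped with a warning. ``fold_scores`` may cover only a sampled
    subset (NaN elsewhere). Incomplete or excluded transcripts contribute
    no row.
    """
    fpkm_by_gene = None
    if expression is not None:
        if expression["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in expression table")
        fpkm_by_gene = dict(zip(expression["gene_id"], expression["fpkm"]))
    rows = []
    seen: set[str] = set()
    n_dropped = 0
    for tx in annotated:
        if tx.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {tx.transcript_id!r}")
        seen.add(tx.transcript_id)
        if not tx.complete or tx.excluded:
            continue
        fpkm = tx.expression
        if fpkm_by_gene is not None:
            if tx.gene_id not in fpkm_by_gene:
                n_dropped += 1
                continue
            fpkm = fpkm_by_gene[tx.gene_id]
        utr5, utr3 = tx.utr5_seq, tx.utr3_seq
        are_hits = scan_are(utr3, tx.transcript_id)
        n_pent = sum(1 for h in are_hits if h.motif_id == "AUUUA")
        n_nona = sum(1 for h in are_hits if h.motif_id == "WWAUUUAWW")
        n_mirna = 0
        if mirnas:
            for name, mseq in mirnas.items():
                n_mirna += len(scan_mirna_sites(utr3, mseq, name, tx.transcript_id))
        uorfs = find_uorfs(tx.spliced_seq, tx.cds_span, tx.transcript_id)
        nmd = classify_nmd(tx.junctions, tx.cds_span, tx.transcript_id)
        comp5 = composition(utr5, "utr5")
        comp3 = composition(utr3, "utr3")
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "group": tx.group,
                "fpkm": fpkm,
                "utr5_len": len(utr5),
                "cds_len": tx.cds_span[1] - tx.cds_span[0],
                "utr3_len": len(utr3),
                "total_len": len(tx.spliced_seq),
                "gc_utr5": comp5.gc_frac,
                "au_utr5": comp5.au_frac,
                "gc_utr3": comp3.gc_frac,
                "au_utr3": comp3.au_frac,
                "are_pentamer_count": n_pent,
                "are_pentamer_density": 1000.0 * n_pent / len(utr3),
                "are_nonamer_count": n_nona,
                "are_nonamer_density": 1000.0 * n_nona / len(utr3),
                "mirna_site_count": n_mirna,
                "mirna_site_density": 1000.0 * n_mirna / len(utr3),
                "n_uorfs": len(uorfs),
                "has_uorf": bool(uorfs),
                "mean_uorf_length": (
                    float(np.mean([u.length for u in uorfs])) if uorfs else np.nan
                ),
                "nmd_flag": nmd.nmd_flag,
                "last_junction_minus_stop": nmd.last_junction_minus_stop,
                "fold_score": (
                    fold_scores.get(tx.transcript_id, np.nan)
                    if fold_scores
                    else np.nan
                ),
            }
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} transcript(s) with no expression record",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def _pairwise_test(x: np.ndarray, y: np.ndarray, test: str) -> float:
    if test == "mannwhitney":
        if np.ptp(np.concatenate([x, y])) == 0:
            # fully degenerate (all ties): no evidence of any difference
            return 1.0
        return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    if test == "ttest":
        return float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    raise ValueError(f"unknown test {test!r}")


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    test: str = "mannwhitney",
    groups: Sequence[str] | None = None,
    bh_correct: bool = False,
) -> GroupComparison:
    """Boxplot-style group summary with pairwise two-sided tests."""
    df = table[["group", feature]].dropna()
    names = list(groups) if groups else sorted(df["group"].unique())
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    values = {g: df.loc[df["group"] == g, feature].to_numpy(float) for g in names}
    for g, v in values.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
    summary = pd.DataFrame(
        {
            "group": names,
            "n": [len(values[g]) for g in names],
            "mean": [float(np.mean(values[g])) for g in names],
            "median": [float(np.median(values[g])) for g in names],
            "q1": [float(np.percentile(values[g], 25)) for g in names],
            "q3": [float(np.percentile(values[g], 75)) for g in names],
        }
    )
    pairs, pvals = [], []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairs.append((a, b))
            pvals.append(_pairwise_test(values[a], values[b], test))
    if bh_correct and pvals:
        pvals = list(sps.false_discovery_control(pvals, method="bh"))
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_value": pvals,
            "stars": [significance_stars(p) for p in pvals],
        }
    )
    return GroupComparison(feature, test, tuple(names), summary, pairwise)


def regress_expression(
    table: pd.DataFrame,
    x_feature: str,
    group: str | None = None,
    dedupe_gene: bool = True,
) -> RegressionResult:
    """OLS of log10(FPKM) on a feature, optionally within one group.

    FPKM <= 0 rows are excluded before the log transform; by default one
    max-expression transcript per gene enters the fit.
    """
    df = table if group is None else table[table["group"] == group]
    df = df[df["fpkm"] > 0].dropna(subset=[x_feature, "fpkm"])
    if dedupe_gene:
        df = df.sort_values("fpkm", ascending=False).drop_duplicates("gene_id")
    if len(df) < 3:
        raise ValueError("need at least 3 observations for regression")
    x = df[x_feature].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError(f"zero-variance feature {x_feature!r}")
    y = np.log10(df["fpkm"].to_numpy(float))
    fit = sps.linregress(x, y)
    return RegressionResult(
        x_name=x_feature,
        y_name="log10_fpkm",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(df),
    )


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return 0.0 if obj == 0 else round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def report(
    table: pd.DataFrame,
    comparisons: Sequence[GroupComparison] = (),
    regressions: Mapping[str, RegressionResult] | None = None,
) -> dict:
    """Machine-readable report bundle (JSON-serialisable, deterministic).

    Includes a per-group summary of median lengths and composition
    alongside the supplied comparisons and regressions.
    """
    group_summary = {}
    for g, sub in table.groupby("group"):
        group_summary[str(g)] = {
            "n_transcripts": int(len(sub)),
            "median_utr5_len": float(sub["utr5_len"].median()),
            "median_cds_len": float(sub["cds_len"].median()),
            "median_utr3_len": float(sub["utr3_len"].median()),
            "mean_au_utr5_pct": float(100 * sub["au_utr5"].mean()),
            "mean_au_utr3_pct": float(100 * sub["au_utr3"].mean()),
            "mean_are_pentamer_density": float(sub["are_pentamer_density"].mean()),
            "mean_are_nonamer_density": float(sub["are_nonamer_density"].mean()),
            "mean_mirna_site_density": float(sub["mirna_site_density"].mean()),
            "pct_with_mirna_site": float(100 * (sub["mirna_site_count"] > 0).mean()),
            "pct_with_uorf": float(100 * sub["has_uorf"].mean()),
            "mean_uorfs": float(sub["n_uorfs"].mean()),
            "pct_nmd_architecture": float(100 * sub["nmd_flag"].mean()),
            "median_fpkm": float(sub["fpkm"].median()),
        }
    bundle = {
        "n_transcripts": int(len(table)),
        "groups": group_summary,
        "comparisons": [
            {
                "feature": c.feature,
                "test": c.test_name,
                "summary": c.summary.to_dict(orient="records"),
                "pairwise": c.pairwise.to_dict(orient="records"),
            }
            for c in comparisons
        ],
        "regressions": {
            label: dict(r.__dict__) for label, r in (regressions or {}).items()
        },
    }
    return _round_floats(bundle)


def write_report(bundle: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)
        fh.write("\n")
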