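"""5'UTR secondary-structure stability scoring.

Two engines are provided:

* ``internal`` — a deterministic Nussinov-style dynamic program maximising
  stacking-weighted Watson-Crick + GU wobble base pairs (GC=3, AU=2, GU=1)
  with a minimum hairpin loop of 3 nt. The score is the negated optimal
  pair weight (dimensionless, <= 0); it is an explicitly-labelled proxy
  for structural stability, not a thermodynamic minimum free energy.
* ``external`` — an adapter around an RNAfold-dialect folder (plain
  sequence on stdin, "structure (mfe)" on stdout) returning mfe in
  kcal/mol.

Scores from the two engines live on different scales and must never be
mixed within one comparison; :class:`FoldResult` carries engine
provenance so downstream code can enforce this.

Because 5'UTR length itself drives any stability score, group comparisons
use :func:`length_matched_sample` to pick an equal number of UTRs per
group from a common length window before folding.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


#: minimum number of unpaired bases inside a hairpin loop
MIN_LOOP = 3

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair weights, indexed by encoded bases; AU=2, GC=3, GU=1
_PAIR_W = np.zeros((4, 4), dtype=np.int64)
_PAIR_W[0, 3] = _PAIR_W[3, 0] = 2
_PAIR_W[1, 2] = _PAIR_W[2, 1] = 3
_PAIR_W[2, 3] = _PAIR_W[3, 2] = 1


@dataclass(frozen=True)
class FoldResult:
    transcript_id: str
    engine: str  # "internal" | "external"
    score: float  # internal: -(weighted pairs); external: mfe kcal/mol
    length: int
    structure: str = ""  # dot-bracket when available


@dataclass(frozen=True)
class LengthMatchedSample:
    group: str
    transcript_ids: tuple[str, ...]
    window: tuple[float, float]


@njit(cache=True)
def _nussinov_dp(enc: np.ndarray, pair_w: np.ndarray, min_loop: int) -> np.ndarray:
    n = enc.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                w = pair_w[enc[i], enc[k]]
                if w == 0:
                    continue
                cand = w + dp[i + 1, k - 1]
                if k < j:
                    cand += dp[k + 1, j]
                if cand > best:
                    best = cand
            dp[i, j] = best
    return dp


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"invalid base for folding: {e.args[0]!r}") from None


def _traceback(enc: np.ndarray, dp: np.ndarray, i: int, j: int, pairs: list) -> None:
    # prefer pairing the 5'-most base, with the smallest partner k, on ties
    while i < j:
        target = dp[i, j]
        if target == 0:
            return
        paired = False
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = _PAIR_W[enc[i], enc[k]]
            if w == 0:
                continue
            cand = w + dp[i + 1, k - 1] + (dp[k + 1, j] if k < j else 0)
            if cand == target:
                pairs.append((i, k))
                _traceback(enc, dp, i + 1, k - 1, pairs)
                i = k + 1
                paired = True
                break
        if not paired:
            i += 1


def fold_internal(seq: str, transcript_id: str = "") -> FoldResult:
    """Score a sequence with the internal weighted base-pair DP.

    Deterministic: identical sequence gives identical score and
    dot-bracket. Unpairable sequences score 0.
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    enc = _encode(seq)
    n = enc.shape[0]
    if n <= MIN_LOOP + 1:
        return FoldResult(transcript_id, "internal", 0.0, n, "." * n)
    dp = _nussinov_dp(enc, _PAIR_W, MIN_LOOP)
    pairs: list[tuple[int, int]] = []
    _traceback(enc, dp, 0, n - 1, pairs)
    structure = ["."] * n
    for a, b in pairs:
        structure[a], structure[b] = "(", ")"
    return FoldResult(transcript_id, "internal", -float(dp[0, n - 1]), n, "".join(structure))


class RNAfoldAdapter:
    """Subprocess adapter for an RNAfold-dialect external folder.

    Contract: sequence on stdin, output containing a line
    ``<structure> (<mfe>)``; mfe parsed as kcal/mol.
    """

    def __init__(self, executable: str = "RNAfold", extra_args: Sequence[str] = ("--noPS",)):
        self.executable = executable
        self.extra_args = tuple(extra_args)

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def __call__(self, seq: str) -> tuple[str, float]:
        proc = subprocess.run(
            [self.executable, *self.extra_args],
            input=seq + "\n",
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"external folder failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        return self._parse(proc.stdout)

    @staticmethod
    def _parse(out: str) -> tuple[str, float]:
        for line in out.splitlines():
            line = line.strip()
            if "(" in line and line.rsplit("(", 1)[1].rstrip(")").strip().lstrip("-").replace(".", "").isdigit():
                structure, mfe_part = line.rsplit("(", 1)
                return structure.strip(), float(mfe_part.rstrip(")").strip())
        raise RuntimeError(f"could not parse folder output: {out!r}")


def fold_external(
    seq: str,
    adapter: Callable[[str], tuple[str, float]],
    transcript_id: str = "",
) -> FoldResult:
    """Fold via an external engine adapter; errors propagate (no silent
    fallback once a run has started)."""
    structure, mfe = adapter(seq)
    return FoldResult(transcript_id, "external", mfe, len(seq), structure)


def make_folder(engine: str = "internal", adapter: RNAfoldAdapter | None = None):
    """Resolve a folding callable at startup.

    Requesting the external engine when it is unavailable degrades
    gracefully to the internal DP with a warning — but only here, at
    startup; an engine failing mid-run raises.
    """
    if engine == "internal":
        return fold_internal
    if engine == "external":
        adapter = adapter or RNAfoldAdapter()
        if not adapter.available():
            warnings.warn(
                f"external folder {adapter.executable!r} not found; "
                "falling back to the internal scoring engine",
                RuntimeWarning,
                stacklevel=2,
            )
            return fold_internal
        return lambda seq, transcript_id="": fold_external(seq, adapter, transcript_id)
    raise ValueError(f"unknown folding engine: {engine!r}")


def length_matched_sample(
    lengths_by_group: Mapping[str, Mapping[str, int]],
    k: int = 50,
    seed: int = 0,
    window: tuple[float, float] | None = None,
    allow_smaller: bool = False,
) -> list[LengthMatchedSample]:
    """Pick ``k`` transcripts per group from a shared length window.

    The default window is the intersection of the per-group IQRs of the
    length distributions; when that intersection is empty (e.g. one group
    is much shorter than the rest) it relaxes to the 10th-90th percentile
    intersection, then to the full-range intersection, with a warning.
    If a group has fewer than ``k`` transcripts in the window, either
    ``k`` is reduced to the attainable value (``allow_smaller=True``) or
    a ValueError reporting it is raised.
    """
    if window is None:
        arrays = [
            np.asarray(list(lens.values()), dtype=float)
            for lens in lengths_by_group.values()
        ]
        for q_lo, q_hi in ((25, 75), (10, 90), (0, 100)):
            cand = (
                max(np.percentile(a, q_lo) for a in arrays),
                min(np.percentile(a, q_hi) for a in arrays),
            )
            if cand[0] <= cand[1]:
                if (q_lo, q_hi) != (25, 75):
                    warnings.warn(
                        "per-group IQRs do not intersect; relaxed the length "
                        f"window to the {q_lo}-{q_hi} percentile intersection",
                        stacklevel=2,
                    )
                window = cand
                break
    if window is None:
        raise ValueError("group length distributions do not overlap at all")
    lo, hi = window
    if lo > hi:
        raise ValueError(
            f"group length distributions do not overlap: empty window ({lo}, {hi})"
        )
    eligible = {
        g: sorted(t for t, L in lens.items() if lo <= L <= hi)
        for g, lens in lengths_by_group.items()
    }
    attainable = min(len(v) for v in eligible.values())
    if attainable < k:
        if not allow_smaller:
            raise ValueError(
                f"insufficient transcripts in window {window}: attainable k={attainable}"
            )
        k = attainable
    if k == 0:
        raise ValueError(f"no transcripts fall in the common window {window}")
    rng = np.random.default_rng(seed)
    out = []
    for g, tids in eligible.items():
        sel = rng.choice(len(tids), size=k, replace=False)
        out.append(LengthMatchedSample(g, tuple(tids[i] for i in sorted(sel)), window))
    return out
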