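"""Strain-to-strain comparison of origin firing.

Three statistics compare a mutant's per-origin relative copy numbers with a
wild-type control measured in the same way:

* **RFOF** (Relative Fraction of Origins Fired): per origin,
  ``(mutant mean - WT mean) x 100``.  Under the HU-arrest copy-number model
  the window mean approximates ``(1 + f) / mean copy``, so the difference
  scales with the change in the fraction of cells that fired the origin.
* A **one-sided Wilcoxon signed-rank test** of the RFOF values against the
  alternative that their true median exceeds zero.
* The **relative activation score** of a target origin (default ARS608, the
  dormant telomere-proximal origin on chromosome VI-right) against a nearby
  efficient reference origin (default ARS607): the mutant's target/reference
  score ratio normalized to the wild type's.  The normalization is either
  subtract-WT-then-x100 (the RFOF-style analysis, the default) or a plain
  WT-ratio; both are recorded in the result because the published description
  is ambiguous between them.

All three consume *unscaled* relative copy numbers; the 1.25 scatter-plot
scaling never enters.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .origins import OriginScoreTable

__all__ = [
    "DeltaTable",
    "SignedRankResult",
    "ActivationScore",
    "relative_fraction_fired",
    "wilcoxon_signed_rank_greater",
    "signed_rank_null_pmf",
    "ars_activation_score",
]

EXACT_N_MAX = 25  # exact signed-rank null up to here; normal approximation beyond


@dataclass
class DeltaTable:
    """Per-origin RFOF of one mutant against one wild type."""

    mutant_id: str
    wt_id: str
    rfof: pd.Series  # indexed by origin name
    n_dropped_masked: int = 0

    @property
    def n_origins(self) -> int:
        return len(self.rfof)

    def write_tsv(self, path: str | os.PathLike) -> None:
        out = self.rfof.rename("rfof").rename_axis("origin").reset_index()
        out.insert(0, "wt", self.wt_id)
        out.insert(0, "mutant", self.mutant_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class SignedRankResult:
    n_used: int           # after zero removal
    statistic: float      # W+ = sum of positive ranks
    p_value: float        # upper tail, P(W+ >= observed)
    method: str           # "exact" or "normal_approx"

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class ActivationScore:
    mutant_id: str
    wt_id: str
    target_origin: str
    reference_origin: str
    score: float
    mode: str  # "subtract_x100" or "ratio"
    mutant_ratio: float  # target/reference in the mutant
    wt_ratio: float      # target/reference in the WT

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _shared_unmasked(mutant: OriginScoreTable, wt: OriginScoreTable):
    shared = mutant.table.index.intersection(wt.table.index)
    m = mutant.scores.loc[shared]
    w = wt.scores.loc[shared]
    ok = m.notna() & w.notna()
    return m[ok], w[ok], int((~ok).sum())


def relative_fraction_fired(mutant: OriginScoreTable,
                            wt: OriginScoreTable) -> DeltaTable:
    """Per-origin ``(mutant - WT) x 100`` on shared, unmasked origins.

    Origins masked (undefined window mean) in either strain are dropped and
    counted in ``n_dropped_masked``.  Raises if a caller hands in scaled
    scores: the scatter-plot scaling must never leak into RFOF.
    """
    for t in (mutant, wt):
        # guard against a table whose relative_copy_number column already
        # carries the scatter-plot scale factor
        if "scaled" in t.table and t.scale_factor != 1.0:
            unscaled = t.table["relative_copy_number"].dropna()
            if len(unscaled) and np.allclose(unscaled, t.table["scaled"].dropna()):
                raise ValueError(
                    f"score table for {t.strain_id} appears to hold scaled "
                    f"values in relative_copy_number: use unscaled scores")
    m, w, dropped = _shared_unmasked(mutant, wt)
    if len(m) == 0:
        raise ValueError(
            f"no shared unmasked origins between {mutant.strain_id} and {wt.strain_id}")
    rfof = (m - w) * 100.0
    rfof.name = "rfof"
    return DeltaTable(mutant_id=mutant.strain_id, wt_id=wt.strain_id,
                      rfof=rfof, n_dropped_masked=dropped)


def signed_rank_null_pmf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ for given (possibly tied) ranks.

    Under H0 each observation is positive or negative with probability 1/2
    independently, so W+ is a sum over a random subset of the ranks.  Average
    ranks from ties are half-integers; doubling makes them integers, and the
    distribution is built by dynamic programming (polynomial multiplication)
    over the doubled ranks.  Returns ``(support, pmf)`` on the original scale.
    """
    r2 = np.rint(2 * np.asarray(ranks, dtype=np.float64)).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    top = 0
    for r in r2:
        counts[r:top + r + 1] += counts[:top + 1]
        top += r
    pmf = counts / counts.sum()
    support = np.arange(total + 1) / 2.0
    return support, pmf


def wilcoxon_signed_rank_greater(deltas: Sequence[float]) -> SignedRankResult:
    """One-sided Wilcoxon signed-rank test, alternative: true median > 0.

    Zeros are dropped (standard Wilcoxon convention); tied absolute values
    receive average ranks.  For ``n_used <= 25`` the p-value is the exact
    upper tail ``P(W+ >= w)`` of the enumerated null; beyond that a normal
    approximation with continuity correction and tie-corrected variance is
    used.  All values zero (or empty) yields ``p = 1``.
    """
    d = np.asarray(list(deltas), dtype=np.float64)
    if d.size == 0:
        raise ValueError("need at least one value")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(n_used=0, statistic=0.0, p_value=1.0, method="exact")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        support, pmf = signed_rank_null_pmf(ranks)
        p = float(pmf[support >= w_plus - 1e-9].sum())
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
        z = (w_plus - mean - 0.5) / math.sqrt(var)
        p = float(sps.norm.sf(z))
        method = "normal_approx"
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return SignedRankResult(n_used=n, statistic=w_plus, p_value=p, method=method)


def ars_activation_score(
    mutant: OriginScoreTable,
    wt: OriginScoreTable,
    target: str = "ARS608",
    reference: str = "ARS607",
    mode: str = "subtract_x100",
) -> ActivationScore:
    """Relative activation of ``target`` against ``reference``, WT-normalized.

    Let ``q = score(target) / score(reference)`` within each strain.  In
    ``subtract_x100`` mode (default) the result is ``(q_mut - q_wt) x 100``;
    in ``ratio`` mode it is ``q_mut / q_wt``.  A strain compared against
    itself scores 0 (subtract mode) or 1 (ratio mode).
    """
    if mode not in ("subtract_x100", "ratio"):
        raise ValueError(f"mode must be 'subtract_x100' or 'ratio', got {mode!r}")
    vals = {}
    for table in (mutant, wt):
        for name in (target, reference):
            v = table.score(name)  # KeyError if absent
            if math.isnan(v):
                raise ValueError(
                    f"origin {name!r} is masked in {table.strain_id}'s score table")
            vals[(table.strain_id, name)] = v
        if vals[(table.strain_id, reference)] <= 0:
            raise ValueError(
                f"reference origin {reference!r} has non-positive score in "
                f"{table.strain_id}")
    q_mut = vals[(mutant.strain_id, target)] / vals[(mutant.strain_id, reference)]
    q_wt = vals[(wt.strain_id, target)] / vals[(wt.strain_id, reference)]
    score = (q_mut - q_wt) * 100.0 if mode == "subtract_x100" else q_mut / q_wt
    return ActivationScore(
        mutant_id=mutant.strain_id, wt_id=wt.strain_id, target_origin=target,
        reference_origin=reference, score=float(score), mode=mode,
        mutant_ratio=float(q_mut), wt_ratio=float(q_wt))
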