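import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

import orifire as ofr


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)

def brute_force_bin_counts(intervals, layout, mode):
    """Per-fragment loop over every bin; 'overlap' counts any >=1 bp intersection."""
    out = {c: np.zeros(layout.n_bins(c), dtype=int) for c in layout.names}
    bs = layout.bin_size
    for chrom, start, end in intervals:
        chrom = layout.canonical(chrom)
        if mode == "midpoint":
            mid = (start + end - 1) // 2
            out[chrom][mid // bs] += 1
        else:
            for k in range(layout.n_bins(chrom)):
                b_lo = k * bs
                b_hi = min(b_lo + bs, layout.length(chrom))
                if min(end, b_hi) - max(start, b_lo) >= 1:
                    out[chrom][k] += 1
    return out


def per_base_window_mean(ratio, chrom, lo, hi):
    """Average the per-base expansion of the binned ratio over [lo, hi)."""
    layout = ratio.layout
    lo = max(0, lo)
    hi = min(layout.length(chrom), hi)
    vals = []
    for pos in range(lo, hi):
        k = pos // layout.bin_size
        v = ratio.values[chrom][k]
        if not np.isnan(v):
            vals.append(v)
    return float(np.mean(vals)) if vals else float("nan")


def wilcoxon_enumeration_p(deltas):
    """Exact upper-tail p by enumerating all 2^n sign assignments."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            hits += 1
    return hits / 2 ** n


# ---------------------------------------------------------------------------
# shared fixtures

@pytest.fixture
def toy_layout():
    return ofr.GenomeLayout((("chrI", 1000),), bin_size=250)


@pytest.fixture
def two_chrom_layout():
    return ofr.GenomeLayout((("chrI", 2000), ("chrII", 1300)), bin_size=250)


@pytest.fixture(scope="session")
def two_strain():
    return ofr.make_fixture("two_strain_default", seed=17, depth=1e6)


def constant_ratio(layout, value=1.0):
    values = {c: np.full(layout.n_bins(c), float(value)) for c in layout.names}
    reasons = {c: np.zeros(layout.n_bins(c), dtype=np.uint8) for c in layout.names}
    return ofr.RatioTrack(layout=layout, values=values, mask_reason=reasons)


@pytest.fixture
def make_constant_ratio():
    return constant_ratio
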