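"""Synthetic replication-in-HU data with closed-form expectations.

The generator emulates the statistical structure the S/G1 pipeline assumes.
Cells arrested in early S with hydroxyurea have replicated only the DNA near
origins that fired before the arrest: the height of the coverage peak at an
origin tracks the fraction of cells *f* in which it fired, and the peak width
tracks how far forks travel before stalling.

Model
-----
Each origin ``i`` fires independently in a cell with probability ``f_i``.  A
fired origin replicates a symmetric interval ``[m_i - D, m_i + D]`` around its
midpoint, with the travel distance ``D`` drawn from a normal distribution
truncated at zero (a point mass when ``sd = 0``).  A position is replicated if
any origin's fork reached it, so its expected copy number is

    c(x) = 1 + P(replicated at x) = 1 + (1 - prod_i (1 - f_i * q_i(x)))

with ``q_i(x) = P(D >= |x - m_i|)``.  G1 is uniform copy 1.  Sequencing reads
are Poisson per bin at rates proportional to copy number times bin width,
normalized to the sample's expected depth — so the expected pipeline ratio at
``x`` is ``c(x) / c_bar`` with ``c_bar`` the length-weighted genome mean copy.
That closed form (``expected_ratio``) is the noise-free target of the full
coverage pipeline and serves as its oracle.

A per-cell mode simulates ``n_cells`` explicit cells (Bernoulli firing,
sampled fork distances) as a stochastic oracle for the closed form.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .coverage import (MASK_NONE, BinnedTrack, FragmentSet, GenomeLayout,
                       RatioTrack)
from .origins import (OriginRecord, OriginScoreTable, OriginSet,
                      origin_window_mean, parse_origins, score_table)

__all__ = [
    "SimOrigin",
    "StrainSim",
    "CopyProfile",
    "expected_copy",
    "expected_ratio",
    "estimate_firing_prob",
    "sample_counts",
    "sample_fragments",
    "per_cell_copy",
    "make_fixture",
    "Fixture",
    "load_sim_config",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class SimOrigin:
    """An origin with a per-cell firing probability."""

    name: str
    chromosome: str
    midpoint: int     # bp, 0-based
    firing_prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.firing_prob <= 1.0:
            raise ValueError(f"{self.name}: firing_prob {self.firing_prob} not in [0,1]")


@dataclass(frozen=True)
class StrainSim:
    """Simulator configuration for one strain's paired G1/S samples.

    Parameters
    ----------
    fork_distance_mean, fork_distance_sd
        Fork travel under HU, bp; distance ~ Normal truncated at 0, or exactly
        the mean when sd = 0.
    n_cells
        Cells in per-cell mode (the stochastic oracle).
    depth
        Expected fragments per sample.
    fragment_length
        Length of emitted fragments (fragment emission only; binned counts
        place reads by bin directly).
    """

    strain_id: str
    layout: GenomeLayout
    origins: tuple[SimOrigin, ...]
    fork_distance_mean: float = 6000.0
    fork_distance_sd: float = 1000.0
    n_cells: int = 10_000
    depth: float = 1e6
    fragment_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fork_distance_mean <= 0:
            raise ValueError("fork_distance_mean must be positive")
        if self.fork_distance_sd < 0:
            raise ValueError("fork_distance_sd must be non-negative")
        if self.n_cells < 1 or self.depth <= 0:
            raise ValueError("n_cells >= 1 and depth > 0 required")
        for o in self.origins:
            chrom = self.layout.canonical(o.chromosome)
            if not 0 <= o.midpoint < self.layout.length(chrom):
                raise ValueError(f"origin {o.name}: midpoint outside {chrom}")

    def with_firing_prob(self, origin_name: str, f: float,
                         strain_id: str | None = None) -> "StrainSim":
        """Copy of this strain with one origin's firing probability changed."""
        new = tuple(replace(o, firing_prob=f) if o.name == origin_name else o
                    for o in self.origins)
        if not any(o.name == origin_name for o in self.origins):
            raise KeyError(f"origin {origin_name!r} not in strain {self.strain_id}")
        return replace(self, origins=new,
                       strain_id=strain_id or f"{self.strain_id}_f{f:g}")


@dataclass
class CopyProfile:
    """Expected per-bin copy number in [1, 2] plus the genome mean."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]
    mean_copy: float

    def genome_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.layout.names])


def _travel_sf(dist: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """P(fork travel >= dist) for Normal(mean, sd) truncated at 0."""
    if sd == 0:
        return (dist <= mean).astype(np.float64)
    # survival of the truncated normal: Phi((mean - d)/sd) / Phi(mean/sd)
    return sps.norm.cdf((mean - dist) / sd) / sps.norm.cdf(mean / sd)


def expected_copy(sim: StrainSim) -> CopyProfile:
    """Closed-form expected copy number per bin (evaluated at bin midpoints)."""
    values: dict[str, np.ndarray] = {}
    for chrom in sim.layout.names:
        x = sim.layout.bin_midpoints(chrom)
        p_not = np.ones_like(x)
        for o in sim.origins:
            if sim.layout.canonical(o.chromosome) != chrom or o.firing_prob == 0:
                continue
            q = _travel_sf(np.abs(x - o.midpoint),
                           sim.fork_distance_mean, sim.fork_distance_sd)
            p_not *= 1.0 - o.firing_prob * q
        values[chrom] = 1.0 + (1.0 - p_not)
    widths = {c: sim.layout.bin_widths(c) for c in sim.layout.names}
    weighted = sum(float(np.dot(values[c], widths[c])) for c in sim.layout.names)
    mean_copy = weighted / sim.layout.total_length
    return CopyProfile(layout=sim.layout, values=values, mean_copy=mean_copy)


def expected_ratio(sim: StrainSim) -> RatioTrack:
    """The noise-free S/G1 ratio the pipeline targets: c(x) / mean copy."""
    prof = expected_copy(sim)
    values = {c: v / prof.mean_copy for c, v in prof.values.items()}
    reasons = {c: np.zeros(len(v), dtype=np.uint8) for c, v in values.items()}
    return RatioTrack(layout=sim.layout, values=values, mask_reason=reasons)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def per_cell_copy(sim: StrainSim,
                  rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Empirical mean copy per bin over ``n_cells`` simulated cells.

    Each cell fires each origin independently (Bernoulli ``f``), draws one
    symmetric fork distance per fired origin, and replicates the union of the
    reached intervals; the returned per-bin mean over cells converges to
    :func:`expected_copy` as ``n_cells`` grows.
    """
    if rng is None:
        rng = _substreams(sim.seed, 3)[2]
    mean, sd = sim.fork_distance_mean, sim.fork_distance_sd
    out: dict[str, np.ndarray] = {}
    for chrom in sim.layout.names:
        x = sim.layout.bin_midpoints(chrom)
        replicated = np.zeros((sim.n_cells, len(x)), dtype=bool)
        for o in sim.origins:
            if sim.layout.canonical(o.chromosome) != chrom or o.firing_prob == 0:
                continue
            fired = rng.random(sim.n_cells) < o.firing_prob
            if sd == 0:
                dist = np.full(sim.n_cells, float(mean))
            else:
                a = -mean / sd
                dist = sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                         size=sim.n_cells, random_state=rng)
            reach = np.abs(x[None, :] - o.midpoint) <= dist[:, None]
            replicated |= fired[:, None] & reach
        out[chrom] = 1.0 + replicated.mean(axis=0)
    return out


def sample_counts(sim: StrainSim,
                  mode: str = "poisson") -> tuple[BinnedTrack, BinnedTrack]:
    """Draw paired raw G1/S bin counts; identical seed gives identical tracks.

    G1 counts are Poisson with rate proportional to bin width (uniform copy
    1); S counts are Poisson with rate proportional to copy x width.  In
    ``poisson`` mode the copy profile is the closed form; in ``per_cell`` mode
    it is accumulated over ``n_cells`` explicit cells first.  G1 and S use
    independent substreams derived from the master seed.
    """
    if mode not in ("poisson", "per_cell"):
        raise ValueError(f"mode must be 'poisson' or 'per_cell', got {mode!r}")
    rng_g1, rng_s, rng_cells = _substreams(sim.seed, 3)
    layout = sim.layout
    widths = {c: layout.bin_widths(c).astype(np.float64) for c in layout.names}
    if mode == "poisson":
        copy = expected_copy(sim).values
    else:
        copy = per_cell_copy(sim, rng_cells)
    total_g1 = float(layout.total_length)
    total_s = sum(float(np.dot(copy[c], widths[c])) for c in layout.names)
    g1_vals, s_vals = {}, {}
    for chrom in layout.names:
        g1_vals[chrom] = rng_g1.poisson(sim.depth * widths[chrom] / total_g1)
        s_vals[chrom] = rng_s.poisson(
            sim.depth * copy[chrom] * widths[chrom] / total_s)
    g1 = BinnedTrack(layout=layout, values=g1_vals,
                     total=float(sum(v.sum() for v in g1_vals.values())), kind="raw")
    s = BinnedTrack(layout=layout, values=s_vals,
                    total=float(sum(v.sum() for v in s_vals.values())), kind="raw")
    return g1, s


def sample_fragments(sim: StrainSim,
                     mode: str = "poisson") -> tuple[FragmentSet, FragmentSet]:
    """Emit the sampled counts as fragment intervals for the coverage module.

    Each counted read becomes a fragment whose midpoint is uniform within its
    bin, clipped to the chromosome, so midpoint-mode binning recovers the
    sampled counts (up to clipping at chromosome ends).
    """
    g1_track, s_track = sample_counts(sim, mode=mode)
    rng = _substreams(sim.seed ^ 0x5F5E100, 1)[0]
    out = []
    for track, phase in ((g1_track, "G1"), (s_track, "S")):
        frags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sim.layout.names:
            counts = track.values[chrom]
            length, bs = sim.layout.length(chrom), sim.layout.bin_size
            ks = np.repeat(np.arange(len(counts)), counts)
            widths = np.minimum(bs, length - ks * bs)
            # integer midpoints uniform within the bin; midpoint-mode binning
            # then recovers the sampled counts exactly away from chromosome ends
            mids = ks * bs + rng.integers(0, widths)
            fl = min(sim.fragment_length, length)
            starts = np.clip(mids - (fl - 1) // 2, 0, length - fl)
            ends = starts + fl
            frags[chrom] = (starts, ends)
        out.append(FragmentSet(sample_id=f"{sim.strain_id}_{phase}",
                               phase=phase, fragments=frags))
    return out[0], out[1]


def estimate_firing_prob(ratio: RatioTrack, origin: OriginRecord,
                         sim: StrainSim) -> float:
    """Estimate an isolated origin's firing fraction from a pipeline ratio track.

    Inverts the copy model: at positions forks from a fired origin almost
    surely reach, the expected ratio is ``(1 + f) / c_bar``, so
    ``f_hat = r * c_bar - 1`` with ``r`` the mean ratio over that plateau and
    ``c_bar`` the strain's closed-form genome-mean copy.  The plateau
    half-width is ``fork_distance_mean - 3 * fork_distance_sd`` (at least
    500 bp): the distance a fired fork reaches with probability ~0.999.
    Averaging over the whole plateau rather than a fixed 1 kb window uses all
    bins that carry information about ``f``.  Valid only where no other
    origin's forks plausibly reach.
    """
    half = max(500.0, sim.fork_distance_mean - 3.0 * sim.fork_distance_sd)
    r, _ = origin_window_mean(ratio, origin, window=int(2 * half))
    return r * expected_copy(sim).mean_copy - 1.0


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_NAMES = ("two_strain_default", "ars_toy", "edge_cases")


@dataclass
class Fixture:
    """A self-contained test scenario: layout, origins, strain pair, oracles."""

    name: str
    layout: GenomeLayout
    origins: OriginSet
    sims: dict[str, StrainSim]          # "WT" and "mutant"
    expected_scores: dict[str, OriginScoreTable]
    origins_table: pd.DataFrame

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "chrom.sizes"), "w") as fh:
            for chrom, length in self.layout.chromosomes:
                fh.write(f"{chrom}\t{length}\n")
        self.origins_table.to_csv(
            os.path.join(out_dir, "origins.tsv"), sep="\t", index=False)
        for label, table in self.expected_scores.items():
            table.write_tsv(os.path.join(out_dir, f"expected_scores_{label}.tsv"))


def _origin_rows(origins: Iterable[SimOrigin], half_width: int = 150):
    rows = []
    for o in origins:
        rows.append((o.chromosome, o.midpoint + 1 - half_width,
                     o.midpoint + 1 + half_width, "Confirmed", o.name))
    return rows


def _build_fixture(name: str, layout: GenomeLayout, wt_origins, mut_origins,
                   extra_rows=(), seed: int = 17, depth: float = 1e6,
                   fork_mean: float = 6000.0, fork_sd: float = 1000.0) -> Fixture:
    wt = StrainSim(strain_id="WT", layout=layout, origins=tuple(wt_origins),
                   fork_distance_mean=fork_mean, fork_distance_sd=fork_sd,
                   depth=depth, seed=seed)
    mut = StrainSim(strain_id="mutant", layout=layout, origins=tuple(mut_origins),
                    fork_distance_mean=fork_mean, fork_distance_sd=fork_sd,
                    depth=depth, seed=seed + 1)
    rows = _origin_rows(wt_origins) + list(extra_rows)
    table = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                        "status", "name"])
    origin_set = parse_origins(table, layout)
    expected = {
        label: score_table(expected_ratio(sim), origin_set,
                           strain_id=f"{label}_expected")
        for label, sim in (("WT", wt), ("mutant", mut))
    }
    return Fixture(name=name, layout=layout, origins=origin_set,
                   sims={"WT": wt, "mutant": mut},
                   expected_scores=expected, origins_table=table)


def make_fixture(name: str, seed: int = 17, depth: float = 1e6) -> Fixture:
    """Build a named test fixture with closed-form expected score tables.

    ``two_strain_default`` — a ~300 kb two-chromosome toy genome echoing the
    chromosome VI-right geometry: an efficient early origin (ARS607-like,
    f = 0.9) 12 kb from a dormant origin (ARS608-like, f = 0.1 in WT vs 0.7 in
    the mutant), plus interior origins with equal firing in both strains.
    ``ars_toy`` — the minimal ARS607/ARS608 pair on one chromosome.
    ``edge_cases`` — origins near chromosome ends and a Dubious record, for
    window-truncation and filtering behavior.
    """
    if name == "two_strain_default":
        layout = GenomeLayout((("chrV", 100_000), ("chrVI", 200_000)), bin_size=250)
        base = [
            SimOrigin("ARS510", "chrV", 50_000, 0.6),
            SimOrigin("ARS606", "chrVI", 60_000, 0.5),
            SimOrigin("ARS607", "chrVI", 120_000, 0.9),
            SimOrigin("ARS608", "chrVI", 132_000, 0.1),
            SimOrigin("ARS609", "chrVI", 170_000, 0.2),
        ]
        mut = [replace(o, firing_prob=0.7) if o.name == "ARS608" else o
               for o in base]
        return _build_fixture(name, layout, base, mut, seed=seed, depth=depth)
    if name == "ars_toy":
        layout = GenomeLayout((("chrVI", 150_000),), bin_size=250)
        base = [
            SimOrigin("ARS607", "chrVI", 70_000, 0.9),
            SimOrigin("ARS608", "chrVI", 82_000, 0.1),
        ]
        mut = [replace(o, firing_prob=0.7) if o.name == "ARS608" else o
               for o in base]
        return _build_fixture(name, layout, base, mut, seed=seed, depth=depth)
    if name == "edge_cases":
        layout = GenomeLayout((("chrIII", 60_000),), bin_size=250)
        base = [
            SimOrigin("ARS-edge", "chrIII", 2_000, 0.8),    # 2 kb from the start
            SimOrigin("ARS-mid", "chrIII", 30_000, 0.5),
            SimOrigin("ARS-right", "chrIII", 58_500, 0.4),  # 1.5 kb from the end
        ]
        mut = [replace(o, firing_prob=0.9) if o.name == "ARS-edge" else o
               for o in base]
        extra = [("chrIII", 44_900, 45_100, "Dubious", "ARS-dubious")]
        return _build_fixture(name, layout, base, mut, extra_rows=extra,
                              seed=seed, depth=depth)
    raise ValueError(f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}")


def load_sim_config(path: str | os.PathLike) -> dict[str, StrainSim]:
    """Read strain simulators from a YAML config.

    Layout::

        bin_size: 250
        chromosomes: {chrVI: 200000}
        strains:
          WT:
            seed: 1
            depth: 1.0e6
            fork_distance_mean: 6000
            fork_distance_sd: 1000
            origins:
              - {name: ARS607, chromosome: chrVI, midpoint: 120000, firing_prob: 0.9}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    layout = GenomeLayout(tuple(cfg["chromosomes"].items()),
                          bin_size=int(cfg.get("bin_size", 250)))
    sims = {}
    for strain_id, block in cfg["strains"].items():
        origins = tuple(
            SimOrigin(o["name"], o["chromosome"], int(o["midpoint"]),
                      float(o["firing_prob"]))
            for o in block["origins"])
        casts = {"fork_distance_mean": float, "fork_distance_sd": float,
                 "n_cells": int, "depth": float, "fragment_length": int,
                 "seed": int}
        kwargs = {k: cast(block[k]) for k, cast in casts.items() if k in block}
        sims[strain_id] = StrainSim(strain_id=strain_id, layout=layout,
                                    origins=origins, **kwargs)
    return sims
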