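"""Per-origin scoring of an S/G1 ratio track.

Converts a :class:`~orifire.coverage.RatioTrack` plus an OriDB-style origin
annotation into per-origin relative copy number (the mean S/G1 ratio over a
1 kb window centered at the origin midpoint), the 1.25-scaled values used for
scatter plots, and origin-centered heatmap matrices (10 kb around each
midpoint by default).

OriDB coordinates are 1-based inclusive; internally everything is 0-based
half-open, and the midpoint of an origin spanning ``start..end`` (1-based) is
``floor((start - 1 + end) / 2)`` in 0-based coordinates.  Origins in
subtelomeric X and Y' elements cannot be uniquely mapped and are excluded from
all statistics, either by an explicit name list or by a distance-to-chromosome-
end margin.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import MASK_NONE, GenomeLayout, RatioTrack

__all__ = [
    "OriginRecord",
    "OriginSet",
    "OriginScoreTable",
    "HeatmapMatrix",
    "parse_origins",
    "write_origins",
    "filter_origins",
    "origin_window_mean",
    "score_table",
    "heatmap_matrix",
]

STATUSES = ("Confirmed", "Likely", "Dubious")


@dataclass(frozen=True)
class OriginRecord:
    name: str
    chromosome: str
    start: int  # 1-based inclusive, as annotated
    end: int    # 1-based inclusive
    status: str
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"origin {self.name}: start {self.start} > end {self.end}")
        if self.status not in STATUSES:
            raise ValueError(f"origin {self.name}: unknown status {self.status!r}")

    @property
    def midpoint(self) -> int:
        """0-based midpoint coordinate."""
        return (self.start - 1 + self.end) // 2


@dataclass(frozen=True)
class OriginSet:
    records: tuple[OriginRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate origin names: {dupes}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def active(self) -> tuple[OriginRecord, ...]:
        return tuple(r for r in self.records if not r.excluded)

    def get(self, name: str) -> OriginRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(f"origin {name!r} not in set")


def parse_origins(path_or_df, layout: GenomeLayout) -> OriginSet:
    """Parse an OriDB-style origin table (chromosome, start, end, status, name).

    Accepts a TSV path or a DataFrame; a header row is tolerated.  Chromosome
    names are canonicalized against ``layout``; unknown chromosomes raise.
    """
    cols = ["chromosome", "start", "end", "status", "name"]
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
        df.columns = [c.lower() for c in df.columns]
        provenance = "DataFrame"
    else:
        df = pd.read_csv(path_or_df, sep="\t", header=None, names=cols,
                         dtype=str, comment="#")
        if not str(df.iloc[0]["start"]).lstrip("-").isdigit():  # header row
            df = df.iloc[1:].reset_index(drop=True)
        provenance = str(path_or_df)
    records = []
    for _, row in df.iterrows():
        name = str(row["name"])
        chrom = layout.canonical(str(row["chromosome"]))
        start, end = int(row["start"]), int(row["end"])
        rec = OriginRecord(name=name, chromosome=chrom, start=start, end=end,
                           status=str(row["status"]))
        if not (1 <= rec.start and rec.end <= layout.length(chrom)):
            raise ValueError(f"origin {name}: {start}-{end} out of bounds on {chrom}")
        records.append(rec)
    return OriginSet(records=tuple(records), provenance=provenance)


def write_origins(origins: OriginSet, path: str | os.PathLike) -> None:
    """Write the set back as TSV, with exclusion flags for filtered sets."""
    df = pd.DataFrame(
        [(r.chromosome, r.start, r.end, r.status, r.name,
          int(r.excluded), r.exclusion_reason or "") for r in origins],
        columns=["chromosome", "start", "end", "status", "name",
                 "excluded", "exclusion_reason"])
    df.to_csv(path, sep="\t", index=False)


def filter_origins(
    origins: OriginSet,
    layout: GenomeLayout,
    statuses: Iterable[str] = ("Confirmed",),
    exclusion_list: Iterable[str] = (),
    telomere_margin: int = 0,
) -> OriginSet:
    """Keep requested statuses; mark subtelomeric / listed origins excluded.

    An origin is excluded (kept in the set, flagged, never scored) if its name
    appears in ``exclusion_list`` or its midpoint lies within
    ``telomere_margin`` bp of either chromosome end.  Unknown names in the
    exclusion list warn rather than raise.
    """
    statuses = set(statuses)
    exclusion = set(exclusion_list)
    present = {r.name for r in origins}
    for missing in sorted(exclusion - present):
        warnings.warn(f"exclusion-list origin {missing!r} not in set", stacklevel=2)
    kept = []
    for rec in origins:
        if rec.status not in statuses:
            continue
        if rec.name in exclusion:
            rec = replace(rec, excluded=True, exclusion_reason="listed")
        elif telomere_margin > 0:
            length = layout.length(rec.chromosome)
            if rec.midpoint < telomere_margin or rec.midpoint >= length - telomere_margin:
                rec = replace(rec, excluded=True, exclusion_reason="subtelomeric")
        kept.append(rec)
    desc = (f"{origins.provenance} | statuses={sorted(statuses)} "
            f"excluded_names={len(exclusion)} telomere_margin={telomere_margin}")
    return OriginSet(records=tuple(kept), provenance=desc)


def origin_window_mean(
    ratio: RatioTrack,
    origin: OriginRecord,
    window: int = 1000,
    min_coverage: float = 0.5,
) -> tuple[float, int]:
    """Overlap-weighted mean ratio over ``window`` bp centered at the midpoint.

    Each bin's weight is its bp of overlap with
    ``[midpoint - window//2, midpoint + window//2)``, truncated at chromosome
    ends.  Masked bins carry no weight; if the unmasked weight falls below
    ``min_coverage`` of the requested window the score is undefined (NaN).

    Returns ``(mean, n_bins_used)``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    layout = ratio.layout
    if origin.chromosome not in layout.names:
        raise KeyError(f"origin {origin.name}: chromosome {origin.chromosome!r} "
                       f"absent from track layout")
    length, bs = layout.length(origin.chromosome), layout.bin_size
    lo = max(0, origin.midpoint - window // 2)
    hi = min(length, origin.midpoint - window // 2 + window)
    if lo >= hi:
        return float("nan"), 0
    first, last = lo // bs, (hi - 1) // bs
    ks = np.arange(first, last + 1)
    bin_lo = ks * bs
    bin_hi = np.minimum(bin_lo + bs, length)
    weights = (np.minimum(bin_hi, hi) - np.maximum(bin_lo, lo)).astype(np.float64)
    vals = ratio.values[origin.chromosome][first:last + 1]
    ok = ratio.unmasked(origin.chromosome)[first:last + 1] & (weights > 0)
    used = weights[ok].sum()
    if used < min_coverage * window:
        return float("nan"), int(ok.sum())
    mean = float(np.dot(vals[ok], weights[ok]) / used)
    return mean, int(ok.sum())


@dataclass
class OriginScoreTable:
    """Per-origin relative copy number for one strain.

    ``table`` is indexed by origin name with columns ``chromosome``,
    ``midpoint``, ``relative_copy_number`` (the unscaled window mean, the
    quantity all downstream statistics consume), ``n_bins_used`` and
    ``scaled`` (= relative_copy_number x scale_factor, for scatter plots only).
    """

    strain_id: str
    table: pd.DataFrame
    scale_factor: float = 1.25
    window: int = 1000

    def score(self, origin_name: str) -> float:
        try:
            return float(self.table.loc[origin_name, "relative_copy_number"])
        except KeyError:
            raise KeyError(f"origin {origin_name!r} not in score table "
                           f"for {self.strain_id}") from None

    @property
    def scores(self) -> pd.Series:
        return self.table["relative_copy_number"]

    def write_tsv(self, path: str | os.PathLike) -> None:
        out = self.table.reset_index(names="origin")
        out.insert(0, "strain", self.strain_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike, scale_factor: float = 1.25) -> "OriginScoreTable":
        df = pd.read_csv(path, sep="\t")
        strain = str(df["strain"].iloc[0]) if "strain" in df else "unknown"
        df = df.drop(columns=["strain"], errors="ignore").set_index("origin")
        return cls(strain_id=strain, table=df, scale_factor=scale_factor)


def score_table(
    ratio: RatioTrack,
    origins: OriginSet,
    window: int = 1000,
    scale_factor: float = 1.25,
    strain_id: str = "strain",
) -> OriginScoreTable:
    """One relative-copy-number row per non-excluded origin.

    The ``scaled`` column (x ``scale_factor``, default 1.25 to account for
    replication progression during the HU arrest) is presentation-only; RFOF
    and activation scores always consume the unscaled means.
    """
    rows = {}
    for rec in origins.active:
        mean, n_used = origin_window_mean(ratio, rec, window=window)
        rows[rec.name] = (rec.chromosome, rec.midpoint, mean, n_used,
                          mean * scale_factor)
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["chromosome", "midpoint", "relative_copy_number",
                 "n_bins_used", "scaled"])
    table.index.name = "origin"
    return OriginScoreTable(strain_id=strain_id, table=table,
                            scale_factor=scale_factor, window=window)


@dataclass
class HeatmapMatrix:
    """Origin-centered ratio matrix: one row per origin, one column per bin."""

    origin_names: tuple[str, ...]
    values: np.ndarray  # (n_origins, n_cols) float, NaN where masked
    span: int
    bin_size: int

    @property
    def center_col(self) -> int:
        return self.span // (2 * self.bin_size)

    def to_frame(self) -> pd.DataFrame:
        n_cols = self.values.shape[1]
        offsets = (np.arange(n_cols) - self.center_col) * self.bin_size
        df = pd.DataFrame(self.values, index=list(self.origin_names),
                          columns=[str(o) for o in offsets])
        df.index.name = "origin"
        return df

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")

    def sort_by(self, key: pd.Series) -> "HeatmapMatrix":
        """Reorder rows by an external per-origin key (e.g. WT score), descending."""
        order = key.reindex(list(self.origin_names)).sort_values(ascending=False).index
        idx = [self.origin_names.index(n) for n in order]
        return HeatmapMatrix(tuple(order), self.values[idx], self.span, self.bin_size)

    def plot(self, path: str | os.PathLike, cmap: str = "viridis") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, max(2, 0.12 * len(self.origin_names))))
        im = ax.imshow(self.values, aspect="auto", interpolation="nearest", cmap=cmap)
        ax.set_xlabel(f"offset from origin midpoint ({self.bin_size} bp bins)")
        ax.set_ylabel("origin")
        ax.axvline(self.center_col, color="white", lw=0.5)
        fig.colorbar(im, ax=ax, label="S/G1 ratio")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def heatmap_matrix(ratio: RatioTrack, origins: OriginSet,
                   span: int = 10000) -> HeatmapMatrix:
    """Ratio values for ``span`` bp centered at each non-excluded origin.

    Columns are bins of ``[midpoint - span/2, midpoint + span/2)`` snapped to
    the genome bin grid; the bin containing the midpoint is the center column.
    Columns falling outside the chromosome are masked (NaN).
    """
    bs = ratio.layout.bin_size
    if span % bs != 0:
        raise ValueError(f"span {span} not a multiple of bin size {bs}")
    n_cols = span // bs
    half = n_cols // 2
    active = origins.active
    mat = np.full((len(active), n_cols), np.nan)
    for i, rec in enumerate(active):
        n_bins = ratio.layout.n_bins(rec.chromosome)
        center = rec.midpoint // bs
        ks = np.arange(center - half, center - half + n_cols)
        valid = (ks >= 0) & (ks < n_bins)
        vals = ratio.values[rec.chromosome][ks[valid]]
        mat[i, valid] = vals
    return HeatmapMatrix(tuple(r.name for r in active), mat, span, bs)
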