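"""Binned coverage and normalized S/G1 ratio tracks.

The first stage of the copy-number pipeline: aligned, deduplicated sequencing
fragments for a G1 sample and an HU-arrested early-S sample are counted into
fixed-width genomic bins (250 bp by default), each track is normalized to its
total read count, and the per-bin ratio S/G1 is formed.  After total-read
normalization the ratio approximates relative DNA copy number: bins inside a
region replicated in a fraction *f* of cells sit near ``(1 + f)`` divided by
the genome-mean copy, unreplicated bins sit slightly below 1.

Coordinates are 0-based half-open throughout; bin ``k`` of a chromosome covers
``[k * bin_size, min((k + 1) * bin_size, length))``.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "FragmentSet",
    "BinnedTrack",
    "RatioTrack",
    "read_chrom_sizes",
    "bin_counts",
    "normalize_track",
    "ratio_track",
    "write_bedgraph",
    "read_bedgraph",
    "bin_table",
    "MASK_NONE",
    "MASK_ZERO_G1",
    "MASK_ZERO_BOTH",
    "MASK_REASONS",
]

# mask codes for RatioTrack bins
MASK_NONE = 0
MASK_ZERO_G1 = 1
MASK_ZERO_BOTH = 2
MASK_REASONS = {MASK_NONE: None, MASK_ZERO_G1: "zero_G1", MASK_ZERO_BOTH: "zero_both"}

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII",
          "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI"]
_ROMAN_TO_INT = {r: i + 1 for i, r in enumerate(_ROMAN)}


def _name_aliases(name: str) -> set[str]:
    """All spellings that should resolve to ``name``.

    Yeast chromosome names circulate as ``chrVI``, ``VI``, ``chr6`` and ``6``;
    all four forms map to the same canonical layout name.  Names that are not
    chromosome numbers (e.g. ``chrM``) only alias their own ``chr``-stripped /
    ``chr``-prefixed forms.
    """
    aliases = {name, name.lower()}
    core = name[3:] if name.lower().startswith("chr") else name
    for form in {core, f"chr{core}"}:
        aliases.add(form)
        aliases.add(form.lower())
    num = None
    if core.upper() in _ROMAN_TO_INT:
        num = _ROMAN_TO_INT[core.upper()]
    elif core.isdigit() and 1 <= int(core) <= 16:
        num = int(core)
    if num is not None:
        for form in (str(num), _ROMAN[num - 1]):
            aliases.update({form, f"chr{form}", form.lower(), f"chr{form}".lower()})
    return aliases


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths, plus the bin width.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; lengths in base pairs.
    bin_size
        Bin width in base pairs (default 250, the pipeline's granularity).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 250

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        alias: dict[str, str] = {}
        for n, _ in chroms:
            for a in _name_aliases(n):
                if alias.get(a, n) != n:
                    raise ValueError(f"ambiguous chromosome alias {a!r}")
                alias[a] = n
        object.__setattr__(self, "_alias", alias)
        object.__setattr__(self, "_length", dict(chroms))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        return self._length[self.canonical(chrom)]

    def canonical(self, chrom: str) -> str:
        """Resolve a chromosome name to its canonical layout spelling."""
        try:
            return self._alias[str(chrom)]
        except KeyError:
            try:
                return self._alias[str(chrom).lower()]
            except KeyError:
                raise KeyError(
                    f"unknown chromosome {chrom!r}; layout has {list(self.names)}"
                ) from None

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.bin_size)  # ceil division

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def bin_widths(self, chrom: str) -> np.ndarray:
        """Width in bp of every bin (the last bin may be short)."""
        length, bs = self.length(chrom), self.bin_size
        widths = np.full(self.n_bins(chrom), bs, dtype=np.int64)
        if length % bs:
            widths[-1] = length % bs
        return widths

    def bin_midpoints(self, chrom: str) -> np.ndarray:
        """Midpoint coordinate (bp, float) of every bin."""
        starts = np.arange(self.n_bins(chrom), dtype=np.float64) * self.bin_size
        return starts + self.bin_widths(chrom) / 2.0


def read_chrom_sizes(path: str | os.PathLike, bin_size: int = 250) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from a two-column chrom.sizes TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": int}, comment="#")
    return GenomeLayout(tuple(zip(df["chrom"], df["length"])), bin_size=bin_size)


@dataclass
class FragmentSet:
    """Deduplicated aligned fragments for one sample.

    ``fragments`` maps canonical chromosome name to ``(starts, ends)`` integer
    arrays of 0-based half-open intervals.  Use :meth:`from_intervals`,
    :meth:`from_bed` or :meth:`from_bam` to construct with validation.
    """

    sample_id: str
    phase: str  # "G1" or "S"
    fragments: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if self.phase not in ("G1", "S"):
            raise ValueError(f"phase must be 'G1' or 'S', got {self.phase!r}")

    @property
    def n_fragments(self) -> int:
        return sum(len(s) for s, _ in self.fragments.values())

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int]],
        layout: GenomeLayout,
        sample_id: str = "sample",
        phase: str = "S",
    ) -> "FragmentSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            canon = layout.canonical(chrom)  # KeyError names the chromosome
            start, end = int(start), int(end)
            if not (0 <= start < end <= layout.length(canon)):
                raise ValueError(
                    f"fragment {chrom}:{start}-{end} out of bounds for "
                    f"{canon} (length {layout.length(canon)})"
                )
            by_chrom.setdefault(canon, []).append((start, end))
        frags = {
            c: (np.array([s for s, _ in iv], dtype=np.int64),
                np.array([e for _, e in iv], dtype=np.int64))
            for c, iv in by_chrom.items()
        }
        return cls(sample_id=sample_id, phase=phase, fragments=frags)

    @classmethod
    def from_bed(cls, path: str | os.PathLike, layout: GenomeLayout,
                 sample_id: str | None = None, phase: str = "S") -> "FragmentSet":
        """Read BED3(+) fragment intervals."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={"chrom": str})
        sid = sample_id if sample_id is not None else os.path.basename(str(path))
        return cls.from_intervals(
            zip(df["chrom"], df["start"], df["end"]), layout, sid, phase)

    @classmethod
    def from_bam(cls, path: str | os.PathLike, layout: GenomeLayout,
                 sample_id: str | None = None, phase: str = "S",
                 min_mapq: int = 0) -> "FragmentSet":
        """Read aligned reads from BAM/SAM as fragment intervals.

        Each mapped primary alignment contributes its reference span; mate
        pairs are NOT merged (caller responsibility, matching multicov-style
        counting of individual reads).
        """
        import pysam

        intervals: list[tuple[str, int, int]] = []
        with pysam.AlignmentFile(str(path), check_sq=False) as bam:
            for read in bam:
                if (read.is_unmapped or read.is_secondary or
                        read.is_supplementary or read.mapping_quality < min_mapq):
                    continue
                intervals.append(
                    (read.reference_name, read.reference_start, read.reference_end))
        sid = sample_id if sample_id is not None else os.path.basename(str(path))
        return cls.from_intervals(intervals, layout, sid, phase)

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in self.fragments:
                starts, ends = self.fragments[chrom]
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass
class BinnedTrack:
    """Per-bin values for one sample: raw integer counts or a normalized density."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]
    total: float
    kind: str  # "raw" or "normalized"

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "normalized"):
            raise ValueError(f"kind must be 'raw' or 'normalized', got {self.kind!r}")
        for chrom in self.layout.names:
            v = self.values[chrom]
            if len(v) != self.layout.n_bins(chrom):
                raise ValueError(
                    f"{chrom}: {len(v)} values for {self.layout.n_bins(chrom)} bins")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative bin values")
        if self.kind == "normalized":
            s = sum(float(v.sum()) for v in self.values.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"normalized track sums to {s}, not 1")

    def genome_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.layout.names])


@dataclass
class RatioTrack:
    """Per-bin normalized S/G1 ratio; masked bins are NaN with a reason code."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]          # float, NaN where masked
    mask_reason: dict[str, np.ndarray]     # uint8 codes, see MASK_REASONS

    def __post_init__(self) -> None:
        for chrom in self.layout.names:
            v, m = self.values[chrom], self.mask_reason[chrom]
            if len(v) != self.layout.n_bins(chrom) or len(m) != len(v):
                raise ValueError(f"{chrom}: value/mask length mismatch with layout")
            bad = np.isnan(v) != (m != MASK_NONE)
            if np.any(bad):
                raise ValueError(f"{chrom}: mask codes inconsistent with NaN values")

    def unmasked(self, chrom: str) -> np.ndarray:
        return self.mask_reason[chrom] == MASK_NONE

    @property
    def n_masked(self) -> int:
        return sum(int((m != MASK_NONE).sum()) for m in self.mask_reason.values())


def bin_counts(fragments: FragmentSet, layout: GenomeLayout,
               mode: str = "midpoint") -> BinnedTrack:
    """Count fragments into fixed-width bins.

    ``midpoint`` mode assigns each fragment to the single bin containing
    ``floor((start + end - 1) / 2)``, so bin totals equal the fragment count
    exactly.  ``overlap`` mode increments every bin the fragment intersects by
    at least 1 bp (bedtools-multicov compatible), so totals may exceed it.
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError(f"mode must be 'midpoint' or 'overlap', got {mode!r}")
    bs = layout.bin_size
    values: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        n = layout.n_bins(chrom)
        if chrom not in fragments.fragments:
            values[chrom] = np.zeros(n, dtype=np.int64)
            continue
        starts, ends = fragments.fragments[chrom]
        if len(starts) and (starts.min() < 0 or ends.max() > layout.length(chrom)
                            or np.any(starts >= ends)):
            raise ValueError(f"fragment out of bounds on {chrom}")
        if mode == "midpoint":
            mids = (starts + ends - 1) // 2
            values[chrom] = np.bincount(mids // bs, minlength=n).astype(np.int64)
        else:
            # +1 to every bin in [start//bs, (end-1)//bs] via a difference array
            first = starts // bs
            last = (ends - 1) // bs
            diff = np.zeros(n + 1, dtype=np.int64)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
            values[chrom] = np.cumsum(diff[:-1])
    for chrom in fragments.fragments:
        layout.canonical(chrom)  # reject fragments on unknown chromosomes
    total = float(sum(v.sum() for v in values.values()))
    return BinnedTrack(layout=layout, values=values, total=total, kind="raw")


def normalize_track(track: BinnedTrack) -> BinnedTrack:
    """Divide every bin by the track's total count so the genome sums to 1."""
    total = float(sum(v.sum() for v in track.values.values()))
    if total <= 0:
        raise ValueError("empty sample: total count is zero")
    values = {c: v.astype(np.float64) / total for c, v in track.values.items()}
    return BinnedTrack(layout=track.layout, values=values,
                       total=track.total, kind="normalized")


def ratio_track(s: BinnedTrack, g1: BinnedTrack) -> RatioTrack:
    """Per-bin S/G1 of two normalized tracks; zero-G1 bins are masked, never imputed."""
    if s.layout.names != g1.layout.names or s.layout.bin_size != g1.layout.bin_size:
        raise ValueError(
            f"layout mismatch: S has chromosomes {s.layout.names} bin "
            f"{s.layout.bin_size}, G1 has {g1.layout.names} bin {g1.layout.bin_size}")
    for chrom in s.layout.names:
        if s.layout.n_bins(chrom) != g1.layout.n_bins(chrom):
            raise ValueError(f"layout mismatch on {chrom}: "
                             f"{s.layout.n_bins(chrom)} vs {g1.layout.n_bins(chrom)} bins")
    if s.kind != "normalized" or g1.kind != "normalized":
        raise ValueError("ratio_track requires normalized inputs")
    values: dict[str, np.ndarray] = {}
    reasons: dict[str, np.ndarray] = {}
    for chrom in s.layout.names:
        sv, gv = s.values[chrom], g1.values[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(gv > 0, sv / np.where(gv > 0, gv, 1.0), np.nan)
        reason = np.zeros(len(sv), dtype=np.uint8)
        reason[(gv == 0) & (sv > 0)] = MASK_ZERO_G1
        reason[(gv == 0) & (sv == 0)] = MASK_ZERO_BOTH
        values[chrom] = r
        reasons[chrom] = reason
    return RatioTrack(layout=s.layout, values=values, mask_reason=reasons)


def write_bedgraph(track: RatioTrack, path: str | os.PathLike,
                   precision: int = 6) -> None:
    """Write unmasked bins as 0-based half-open BedGraph intervals."""
    layout = track.layout
    with open(path, "w") as fh:
        for chrom in layout.names:
            v = track.values[chrom]
            ok = track.unmasked(chrom)
            bs, length = layout.bin_size, layout.length(chrom)
            for k in np.flatnonzero(ok):
                start = k * bs
                end = min(start + bs, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v[k]:.{precision}f}\n")


def read_bedgraph(path: str | os.PathLike, layout: GenomeLayout) -> RatioTrack:
    """Read a BedGraph written on this layout's bin grid; absent bins are masked.

    Bins not present in the file are masked ``zero_both`` (reason unknown once
    serialized; the code records only that the bin was undefined).
    """
    values = {c: np.full(layout.n_bins(c), np.nan) for c in layout.names}
    reasons = {c: np.full(layout.n_bins(c), MASK_ZERO_BOTH, dtype=np.uint8)
               for c in layout.names}
    bs = layout.bin_size
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                chrom = layout.canonical(parts[0])
                start, end, val = int(parts[1]), int(parts[2]), float(parts[3])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start % bs != 0:
                raise ValueError(
                    f"{path}:{lineno}: interval start {start} not aligned to "
                    f"{bs} bp bin grid")
            k = start // bs
            expected_end = min(start + bs, layout.length(chrom))
            if end != expected_end:
                raise ValueError(
                    f"{path}:{lineno}: interval end {end} does not match bin "
                    f"end {expected_end}")
            values[chrom][k] = val
            reasons[chrom][k] = MASK_NONE
    return RatioTrack(layout=layout, values=values, mask_reason=reasons)


def bin_table(s_raw: BinnedTrack, g1_raw: BinnedTrack,
              ratio: RatioTrack) -> pd.DataFrame:
    """Per-bin table: chrom, start, end, raw_S, raw_G1, ratio, mask."""
    layout = ratio.layout
    rows = []
    for chrom in layout.names:
        n, bs, length = layout.n_bins(chrom), layout.bin_size, layout.length(chrom)
        starts = np.arange(n) * bs
        ends = np.minimum(starts + bs, length)
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "raw_S": s_raw.values[chrom],
            "raw_G1": g1_raw.values[chrom],
            "ratio": ratio.values[chrom],
            "mask": [MASK_REASONS[c] or "" for c in ratio.mask_reason[chrom]],
        }))
    return pd.concat(rows, ignore_index=True)
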