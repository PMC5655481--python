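"""Coordinate conventions, domain containers, and interval algebra.

All coordinates are 0-based half-open ``[start, end)`` internally.  VCF input
(1-based POS, inclusive INFO/END) is converted at the I/O boundary; BED is
already 0-based half-open and is read natively.  Deletion length is defined as
``end - start`` (symbolic-allele convention used by SV callers), never the
REF/ALT string length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SV_TYPES = ("DEL", "INV", "DUP")

#: hard size bounds applied to every SV call (bp)
SIZE_MIN = 50
SIZE_MAX = 10_000_000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class SVCall:
    """One caller's assertion of one SV in one sample."""

    interval: GenomicInterval
    svtype: str
    caller: str
    sample: str
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"svtype must be one of {SV_TYPES}, got {self.svtype!r}")
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be nonnegative")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class SVSite:
    """A merged population-level SV locus, optionally genotyped.

    ``genotypes`` maps sample id -> diploid alternate-allele dosage in
    {0, 1, 2} or -1 for missing.
    """

    interval: GenomicInterval
    svtype: str
    site_id: str
    genotypes: Mapping[str, int] | None = None
    precise: bool = False
    n_carriers: int | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"svtype must be one of {SV_TYPES}, got {self.svtype!r}")
        if self.genotypes is not None:
            bad = {s: g for s, g in self.genotypes.items() if g not in (-1, 0, 1, 2)}
            if bad:
                raise ValueError(f"dosages must be in {{-1,0,1,2}}: {bad}")

    @property
    def length(self) -> int:
        return self.interval.length

    def with_precise(self, flag: bool = True) -> "SVSite":
        return replace(self, precise=flag)


class PopulationPanel:
    """sample -> breed -> group mapping; groups partition the samples."""

    def __init__(self, frame: pd.DataFrame):
        required = {"sample", "breed", "group"}
        if not required.issubset(frame.columns):
            raise ValueError(f"panel needs columns {sorted(required)}")
        if frame["sample"].duplicated().any():
            dupes = frame.loc[frame["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate samples in panel: {dupes}")
        self.frame = frame.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.frame["sample"].tolist()

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def group_of(self, sample: str) -> str:
        row = self.frame.loc[self.frame["sample"] == sample, "group"]
        if row.empty:
            raise KeyError(sample)
        return row.iloc[0]

    def samples_in(self, group: str) -> list[str]:
        return self.frame.loc[self.frame["group"] == group, "sample"].tolist()

    def group_indices(self, sample_order: Sequence[str]) -> dict[str, np.ndarray]:
        """Indices of each group's samples within ``sample_order``."""
        pos = {s: i for i, s in enumerate(sample_order)}
        out: dict[str, np.ndarray] = {}
        for g in self.groups:
            out[g] = np.array(
                [pos[s] for s in self.samples_in(g) if s in pos], dtype=np.intp
            )
        return out

    def __len__(self) -> int:
        return len(self.frame)


class GenotypeMatrix:
    """Samples x sites diploid dosage matrix.

    ``dosage`` is int16 with values {0, 1, 2} and -1 for missing;
    ``sites`` is a DataFrame with columns chrom/start/end/svtype/site_id,
    sorted by (chrom, start).
    """

    SITE_COLUMNS = ("chrom", "start", "end", "svtype", "site_id")

    def __init__(self, sites: pd.DataFrame, samples: Sequence[str], dosage: np.ndarray):
        sites = sites.reset_index(drop=True)
        for col in self.SITE_COLUMNS:
            if col not in sites.columns:
                raise ValueError(f"sites frame missing column {col!r}")
        dosage = np.asarray(dosage, dtype=np.int16)
        if dosage.shape != (len(samples), len(sites)):
            raise ValueError(
                f"dosage shape {dosage.shape} != (n_samples={len(samples)}, "
                f"n_sites={len(sites)})"
            )
        legal = np.isin(dosage, (-1, 0, 1, 2))
        if not legal.all():
            raise ValueError("dosage values must be in {-1,0,1,2}")
        order = np.lexsort((sites["start"].to_numpy(), sites["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(sites))):
            sites = sites.iloc[order].reset_index(drop=True)
            dosage = dosage[:, order]
        self.sites = sites
        self.samples = list(samples)
        self.dosage = dosage

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.dosage == -1).sum(axis=0) / self.n_samples

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            self.sites.iloc[idx], self.samples, self.dosage[:, idx]
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in names]
        return GenotypeMatrix(self.sites, list(names), self.dosage[idx, :])

    def sites_on(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())

    @classmethod
    def from_sv_sites(
        cls, sv_sites: Iterable[SVSite], samples: Sequence[str]
    ) -> "GenotypeMatrix":
        rows, cols = [], []
        for site in sv_sites:
            if site.genotypes is None:
                raise ValueError(f"site {site.site_id} carries no genotypes")
            rows.append(
                (
                    site.interval.chrom,
                    site.interval.start,
                    site.interval.end,
                    site.svtype,
                    site.site_id,
                )
            )
            cols.append([site.genotypes.get(s, -1) for s in samples])
        sites = pd.DataFrame(rows, columns=list(cls.SITE_COLUMNS))
        dosage = (
            np.array(cols, dtype=np.int16).T
            if cols
            else np.zeros((len(samples), 0), dtype=np.int16)
        )
        return cls(sites, samples, dosage)

    def to_sv_sites(self) -> list[SVSite]:
        out = []
        for j, row in self.sites.iterrows():
            gts = {s: int(self.dosage[i, j]) for i, s in enumerate(self.samples)}
            out.append(
                SVSite(
                    GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    row["svtype"],
                    row["site_id"],
                    genotypes=gts,
                )
            )
        return out


class AnnotationSet:
    """Named interval tracks sharing one chromosome coordinate system.

    Tracks are DataFrames with at least chrom/start/end; the transcript track
    additionally carries strand and tss (the strand-aware transcription start
    coordinate), and may be accompanied by an ``intron`` track.
    """

    def __init__(self, tracks: Mapping[str, pd.DataFrame] | None = None):
        self.tracks: dict[str, pd.DataFrame] = {}
        for name, frame in (tracks or {}).items():
            self.add(name, frame)

    def add(self, name: str, frame: pd.DataFrame) -> None:
        for col in ("chrom", "start", "end"):
            if col not in frame.columns:
                raise ValueError(f"track {name!r} missing column {col!r}")
        if ((frame["end"] - frame["start"]) <= 0).any():
            raise ValueError(f"track {name!r} has empty/negative intervals")
        self.tracks[name] = (
            frame.sort_values(["chrom", "start"]).reset_index(drop=True)
        )

    def __contains__(self, name: str) -> bool:
        return name in self.tracks

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tracks[name]

    def get(self, name: str) -> pd.DataFrame | None:
        return self.tracks.get(name)

    def overlapping(self, name: str, iv: GenomicInterval) -> pd.DataFrame:
        """All intervals of a track overlapping ``iv``."""
        t = self.tracks[name]
        sub = t[t["chrom"] == iv.chrom]
        hit = (sub["start"] < iv.end) & (sub["end"] > iv.start)
        return sub[hit]


@dataclass
class WindowGrid:
    """Tiling (or sliding) windows over a set of chromosomes."""

    chrom_lengths: dict[str, int]
    size: int
    step: int
    windows: list[GenomicInterval] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w.chrom, w.start, w.end) for w in self.windows],
            columns=["chrom", "start", "end"],
        )


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when chromosomes differ.

    The standard symmetric SV-matching criterion: both intervals must be
    covered by the shared span to at least the returned fraction.
    """
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a disjoint sorted list.

    Bookended (touching) intervals merge: {[0,10), [10,20)} -> {[0,20)}.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def make_windows(
    chrom_lengths: Mapping[str, int], size: int, step: int | None = None
) -> WindowGrid:
    """Windows ``[k*step, k*step+size)`` clipped to each chromosome end.

    ``step == size`` (the default) gives a non-overlapping tiling; ``step``
    may be smaller for sliding windows but never larger.
    """
    if step is None:
        step = size
    if not (1 <= step <= size):
        raise ValueError(f"need size >= step >= 1, got size={size}, step={step}")
    windows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has nonpositive length")
        pos = 0
        while pos < length:
            windows.append(GenomicInterval(chrom, pos, min(pos + size, length)))
            pos += step
    return WindowGrid(dict(chrom_lengths), size, step, windows)


def window_index_of(grid: WindowGrid, chrom: str, pos: int) -> int | None:
    """Index of the non-overlapping grid window containing ``pos``.

    Half-open convention: a position at an exact window boundary belongs to
    the right-hand window. Returns None for chromosomes outside the grid.
    """
    if grid.step != grid.size:
        raise ValueError("window membership is only unique on non-overlapping grids")
    length = grid.chrom_lengths.get(chrom)
    if length is None or not (0 <= pos < length):
        return None
    offset = 0
    for c, clen in grid.chrom_lengths.items():
        if c == chrom:
            break
        offset += -(-clen // grid.size)
    return offset + pos // grid.size


def interval_union_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def warn_once(message: str) -> None:
    warnings.warn(message, stacklevel=2)
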