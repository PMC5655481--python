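"""Multi-caller SV consensus: merged, genotyped, and precise sets.

The workflow mirrors a multi-tool SV survey: per sample, calls of the same
type from distinct eligible callers are clustered by reciprocal overlap and
kept when supported by at least ``min_support`` tools; supported calls are
then clustered across samples into population-level sites; a separately
genotyped call set is matched back to the merged set at high reciprocal
overlap; and population QC removes high-missingness and fixed-homozygous
sites before any statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    SIZE_MAX,
    SIZE_MIN,
    AnnotationSet,
    GenomicInterval,
    GenotypeMatrix,
    SVCall,
    SVSite,
    reciprocal_overlap,
)

log = logging.getLogger("svpopdiff")

#: the five discovery tools and their per-type eligibility
DEFAULT_CALLERS: dict[str, frozenset[str]] = {
    "DEL": frozenset({"delly", "breakdancer", "pindel", "cnvnator", "lumpy"}),
    "INV": frozenset({"delly", "breakdancer", "pindel", "lumpy"}),
    "DUP": frozenset({"delly", "pindel"}),
}


@dataclass
class CallerConfig:
    """Support and overlap thresholds for consensus building."""

    eligible: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_CALLERS)
    )
    min_support: int = 2
    merge_ro: float = 0.5
    genotype_ro: float = 0.9

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        most = max((len(c) for c in self.eligible.values()), default=0)
        if self.min_support > most:
            raise ValueError(
                f"min_support {self.min_support} exceeds every type's eligible "
                f"caller count (max {most})"
            )
        for svtype, callers in self.eligible.items():
            if self.min_support > len(callers):
                log.info(
                    "min_support %d exceeds the %d eligible callers for %s; "
                    "no %s call can pass", self.min_support, len(callers),
                    svtype, svtype,
                )
        for name, frac in (("merge_ro", self.merge_ro), ("genotype_ro", self.genotype_ro)):
            if not (0 < frac <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {frac}")


@dataclass
class QCConfig:
    """Population-level site QC applied to the genotyped matrix."""

    max_missing: float = 0.05
    drop_fixed_hom: bool = True
    lqlc_mask: str | None = None
    size_min: int = SIZE_MIN
    size_max: int = SIZE_MAX
    precise_max: int = 60_000
    min_gq: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must be in [0, 1]")
        if not (self.size_min < self.precise_max < self.size_max):
            raise ValueError("need size_min < precise_max < size_max")


def size_filter(calls: Iterable[SVCall], qc: QCConfig | None = None) -> list[SVCall]:
    """Keep calls within the [size_min, size_max] bounds."""
    qc = qc or QCConfig()
    return [c for c in calls if qc.size_min <= c.length <= qc.size_max]


def _cluster_by_ro(
    intervals: Sequence[GenomicInterval], min_ro: float
) -> list[list[int]]:
    """Single-linkage clusters of intervals at reciprocal overlap >= min_ro.

    Sweep by sorted start: reciprocal overlap requires a positive overlap, so
    only intervals whose starts precede the running maximum end can link.
    Union-find keeps the linkage transitive.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (intervals[i].chrom, intervals[i].start))
    active: list[int] = []
    for idx in order:
        iv = intervals[idx]
        active = [
            j
            for j in active
            if intervals[j].chrom == iv.chrom and intervals[j].end > iv.start
        ]
        for j in active:
            if reciprocal_overlap(iv, intervals[j]) >= min_ro:
                union(idx, j)
        active.append(idx)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def _median_interval(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Per-coordinate median representative; robust to one outlier caller."""
    start = int(round(float(np.median([iv.start for iv in intervals]))))
    end = int(round(float(np.median([iv.end for iv in intervals]))))
    if end <= start:  # degenerate medians on crossing members
        end = start + 1
    return GenomicInterval(intervals[0].chrom, start, end)


def support_filter(
    calls: Iterable[SVCall], cfg: CallerConfig | None = None
) -> list[SVCall]:
    """Per-sample multi-tool support rule: an SV stands when called by at
    least ``min_support`` distinct eligible callers at reciprocal overlap
    >= ``merge_ro``; the representative breakpoints are the member medians.
    """
    cfg = cfg or CallerConfig()
    by_key: dict[tuple[str, str], list[SVCall]] = {}
    for call in calls:
        eligible = cfg.eligible.get(call.svtype, frozenset())
        if call.caller not in eligible:
            log.warning(
                "caller %r not eligible for %s; call at %s:%d ignored",
                call.caller, call.svtype, call.interval.chrom, call.interval.start,
            )
            continue
        by_key.setdefault((call.sample, call.svtype), []).append(call)

    supported: list[SVCall] = []
    for (sample, svtype), group in by_key.items():
        intervals = [c.interval for c in group]
        for members in _cluster_by_ro(intervals, cfg.merge_ro):
            callers = {group[i].caller for i in members}
            if len(callers) >= cfg.min_support:
                rep = _median_interval([group[i].interval for i in members])
                supported.append(
                    SVCall(rep, svtype, "+".join(sorted(callers)), sample)
                )
    supported.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.svtype))
    return supported


def build_merged_set(
    supported: Iterable[SVCall], cfg: CallerConfig | None = None
) -> list[SVSite]:
    """Cross-sample single-linkage clustering of supported calls into
    population-level SVSites (one site per cluster, median breakpoints).

    Single-linkage chains can occasionally leave two cluster medians closer
    than the merge threshold even though no pair of their members was; the
    clustering therefore iterates on the representatives until the output
    sites of each svtype are pairwise separated (RO < merge_ro).
    """
    cfg = cfg or CallerConfig()
    calls = list(supported)
    sites: list[SVSite] = []
    for svtype in sorted({c.svtype for c in calls}):
        group = [c for c in calls if c.svtype == svtype]
        member_sets = _cluster_by_ro([c.interval for c in group], cfg.merge_ro)
        while True:
            reps = [
                _median_interval([group[i].interval for i in members])
                for members in member_sets
            ]
            rep_clusters = _cluster_by_ro(reps, cfg.merge_ro)
            if all(len(rc) == 1 for rc in rep_clusters):
                break
            member_sets = [
                [i for k in rc for i in member_sets[k]] for rc in rep_clusters
            ]
        for members, rep in zip(member_sets, reps):
            carriers = {group[i].sample for i in members}
            sites.append(SVSite(rep, svtype, "", n_carriers=len(carriers)))
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.svtype))
    return [
        SVSite(s.interval, s.svtype, f"{s.svtype}_{i:06d}", n_carriers=s.n_carriers)
        for i, s in enumerate(sites)
    ]


def build_genotyped_set(
    merged: Sequence[SVSite],
    genotyped_calls: Sequence[SVSite],
    cfg: CallerConfig | None = None,
) -> list[SVSite]:
    """Keep genotyped sites matching the merged set at reciprocal overlap
    >= ``genotype_ro`` with the same svtype; each merged site absorbs at most
    one genotyped site (best overlap wins, ties to the leftmost genotyped).
    """
    cfg = cfg or CallerConfig()
    pairs: list[tuple[float, int, int]] = []  # (ro, genotyped idx, merged idx)
    for gi, gsite in enumerate(genotyped_calls):
        for mi, msite in enumerate(merged):
            if gsite.svtype != msite.svtype:
                continue
            ro = reciprocal_overlap(gsite.interval, msite.interval)
            if ro >= cfg.genotype_ro:
                pairs.append((ro, gi, mi))
    # greedy best-first assignment; ties broken by leftmost genotyped interval
    pairs.sort(
        key=lambda t: (-t[0], genotyped_calls[t[1]].interval.chrom,
                       genotyped_calls[t[1]].interval.start, t[1])
    )
    used_g: set[int] = set()
    used_m: set[int] = set()
    kept: list[int] = []
    for _, gi, mi in pairs:
        if gi in used_g or mi in used_m:
            continue
        used_g.add(gi)
        used_m.add(mi)
        kept.append(gi)
    kept.sort()
    return [genotyped_calls[i] for i in kept]


def apply_population_filters(
    matrix: GenotypeMatrix,
    qc: QCConfig | None = None,
    annotations: AnnotationSet | None = None,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Remove sites failing population QC; returns the filtered matrix and a
    per-rule removal report.

    Rules, applied in order (a site is attributed to the first that fires):
    missing rate > ``max_missing``; homozygous fixed (alternate dosage 2 in
    every non-missing sample); fixed sites inside the LQLC mask (reference-
    artifact candidates) when a mask track is supplied and ``drop_fixed_hom``
    is off.  A per-genotype GQ floor is a no-op here because genotype
    matrices carry no GQ; this is logged rather than silently skipped.
    """
    qc = qc or QCConfig()
    if matrix.n_sites == 0:
        raise ValueError("matrix has no sites")
    if qc.min_gq is not None:
        log.info("min_gq=%s requested but matrix carries no GQ; rule is a no-op", qc.min_gq)

    miss = matrix.missing_fraction()
    d = matrix.dosage
    nonmiss = d >= 0
    n_nonmiss = nonmiss.sum(axis=0)
    all_hom = (np.where(nonmiss, d, 2) == 2).all(axis=0) & (n_nonmiss > 0)

    report = {"missing_rate": 0, "fixed_hom": 0, "lqlc_fixed": 0}
    drop = np.zeros(matrix.n_sites, dtype=bool)

    rule_missing = miss > qc.max_missing
    report["missing_rate"] = int(rule_missing.sum())
    drop |= rule_missing

    if qc.drop_fixed_hom:
        rule_fixed = all_hom & ~drop
        report["fixed_hom"] = int(rule_fixed.sum())
        drop |= rule_fixed

    if annotations is not None and qc.lqlc_mask and qc.lqlc_mask in annotations:
        mask_track = annotations[qc.lqlc_mask]
        in_mask = np.zeros(matrix.n_sites, dtype=bool)
        for j in range(matrix.n_sites):
            row = matrix.sites.iloc[j]
            sub = mask_track[mask_track["chrom"] == row["chrom"]]
            if ((sub["start"] < row["end"]) & (sub["end"] > row["start"])).any():
                in_mask[j] = True
        rule_lqlc = all_hom & in_mask & ~drop
        report["lqlc_fixed"] = int(rule_lqlc.sum())
        drop |= rule_lqlc

    out = matrix.subset_sites(~drop)
    if out.n_sites == 0:
        log.warning("population filters removed every site")
    return out, report


def split_precise_set(
    sites: Iterable[SVSite], qc: QCConfig | None = None
) -> list[SVSite]:
    """Sites shorter than ``precise_max`` (strict <), flagged precise.

    Stands in for the assembly-refined breakpoint set: short SVs are the ones
    local de novo assembly can resolve to single-nucleotide resolution.
    """
    qc = qc or QCConfig()
    return [s.with_precise() for s in sites if s.length < qc.precise_max]


def consensus_summary(
    merged: Sequence[SVSite],
    precise: Sequence[SVSite],
    genotyped: Sequence[SVSite],
) -> pd.DataFrame:
    """Per-svtype site counts across the three sets (survey-table layout)."""
    rows = []
    for svtype in ("DEL", "INV", "DUP"):
        rows.append(
            {
                "svtype": svtype,
                "merged": sum(s.svtype == svtype for s in merged),
                "precise": sum(s.svtype == svtype for s in precise),
                "genotyped": sum(s.svtype == svtype for s in genotyped),
            }
        )
    return pd.DataFrame(rows)
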