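"""Deletion formation-mechanism classification and SV hotspot scanning.

Deletions arise by four broad mechanisms: NAHR (nonallelic homologous
recombination, long flanking homology), NHR (nonhomologous processes —
NHEJ/FoSTeS/MMBIR — no extended homology), TEI (transposable element
insertion polymorphism; in the pig the hallmark is the ~300 bp SINE), and
VNTR (tandem-repeat expansion/contraction).  The classifier here is a
deliberately simplified, rule-based stand-in for full breakpoint-sequence
pipelines: it decides from annotation tracks (tandem repeats, TE intervals)
and an optional externally supplied flank-homology length, with priority
VNTR > TEI > NAHR > NHR.  Thresholds are configurable; the rules, not the
thresholds, are the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationSet, GenomicInterval, SVSite, WindowGrid, warn_once

MECHANISMS = ("NAHR", "NHR", "TEI", "VNTR")


@dataclass
class HotspotConfig:
    window_size: int = 1_000_000
    count_quantile: float = 0.95
    dominance_fraction: float = 0.5
    enrichment_alpha: float = 1e-6
    te_coverage_min: float = 0.85
    nahr_homology_min: int = 50

    def __post_init__(self) -> None:
        for name, v in (
            ("count_quantile", self.count_quantile),
            ("dominance_fraction", self.dominance_fraction),
        ):
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def classify_mechanism(
    site: SVSite,
    annotations: AnnotationSet,
    flank_homology_bp: int | None = None,
    cfg: HotspotConfig | None = None,
) -> str:
    """Mechanism label for one deletion.

    Priority rules:
      1. VNTR — both breakpoints fall inside one annotated tandem-repeat
         interval (the deletion is a repeat-count change);
      2. TEI  — a single TE interval covers >= ``te_coverage_min`` of the
         deleted span (the deletion removes one TE copy);
      3. NAHR — supplied flank homology >= ``nahr_homology_min`` bp;
      4. NHR  — fall-through;
      NA when neither a TE nor a VNTR track is available.
    """
    if site.svtype != "DEL":
        raise ValueError(f"mechanism classification is defined for DEL, got {site.svtype}")
    cfg = cfg or HotspotConfig()
    have_vntr = "vntr" in annotations
    have_te = "te" in annotations
    if not have_vntr and not have_te:
        return "NA"
    iv = site.interval
    if have_vntr:
        vntr = annotations["vntr"]
        sub = vntr[vntr["chrom"] == iv.chrom]
        contains = (sub["start"] <= iv.start) & (iv.end <= sub["end"])
        if contains.any():
            return "VNTR"
    if have_te:
        hits = annotations.overlapping("te", iv)
        if len(hits):
            ov = (
                np.minimum(hits["end"].to_numpy(), iv.end)
                - np.maximum(hits["start"].to_numpy(), iv.start)
            )
            if (ov / iv.length).max() >= cfg.te_coverage_min:
                return "TEI"
    if flank_homology_bp is not None and flank_homology_bp >= cfg.nahr_homology_min:
        return "NAHR"
    return "NHR"


def classify_all(
    sites: Sequence[SVSite],
    annotations: AnnotationSet,
    homology: Mapping[str, int] | None = None,
    cfg: HotspotConfig | None = None,
) -> pd.DataFrame:
    """Classify every deletion; homology maps site_id -> flank homology bp."""
    homology = homology or {}
    rows = []
    for s in sites:
        if s.svtype != "DEL":
            continue
        label = classify_mechanism(s, annotations, homology.get(s.site_id), cfg)
        rows.append(
            (s.site_id, s.interval.chrom, s.interval.start, s.interval.end,
             s.length, label)
        )
    return pd.DataFrame(
        rows, columns=["site_id", "chrom", "start", "end", "length", "mechanism"]
    )


def mechanism_proportions(
    labelled: Iterable[tuple[str, int]]
) -> pd.DataFrame:
    """Count- and length-fractions per mechanism over non-NA labels.

    Input is (label, length) pairs; each fraction vector sums to 1.
    """
    rows = [(m, ln) for m, ln in labelled if m != "NA"]
    if not rows:
        raise ValueError("no successfully classified deletions")
    frame = pd.DataFrame(rows, columns=["mechanism", "length"])
    counts = frame.groupby("mechanism").size()
    lengths = frame.groupby("mechanism")["length"].sum()
    out = pd.DataFrame(
        {
            "n": counts,
            "count_fraction": counts / counts.sum(),
            "total_length": lengths,
            "length_fraction": lengths / lengths.sum(),
        }
    ).reset_index()
    return out.sort_values("count_fraction", ascending=False).reset_index(drop=True)


def runs_test(sequence: Sequence[int] | np.ndarray) -> tuple[float, float]:
    """Wald–Wolfowitz runs test for randomness of a binary sequence.

    With n1, n2 symbol counts and R observed runs:
    mu = 2 n1 n2/(n1+n2) + 1,
    sigma^2 = 2 n1 n2 (2 n1 n2 - n1 - n2) / ((n1+n2)^2 (n1+n2-1)),
    Z = (R - mu)/sigma, two-sided p from the standard normal.  Clustered
    sequences produce few long runs and strongly negative Z.
    """
    seq = np.asarray(sequence)
    symbols = np.unique(seq)
    if len(symbols) != 2:
        raise ValueError("runs test needs a sequence containing exactly two symbols")
    n1 = int((seq == symbols[0]).sum())
    n2 = int((seq == symbols[1]).sum())
    runs = int(1 + (seq[1:] != seq[:-1]).sum())
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1))
    z = (runs - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def spacing_sequence(starts: Sequence[int] | np.ndarray) -> np.ndarray:
    """Genome-ordered inter-deletion start spacings dichotomized at their
    median (below-median -> 1).  Clustered deletions yield long runs of 1s
    interrupted by long runs of 0s, driving the runs-test Z negative."""
    starts = np.sort(np.asarray(starts))
    gaps = np.diff(starts)
    if len(gaps) < 2:
        raise ValueError("need at least 3 positions for a spacing sequence")
    return (gaps < np.median(gaps)).astype(np.int8)


def window_sv_counts(sites: Sequence[SVSite], grid: WindowGrid) -> np.ndarray:
    """Per-window SV counts; a site belongs to the window containing its
    start (half-open, so a start at an exact boundary counts rightward)."""
    if grid.step != grid.size:
        raise ValueError("hotspot counting requires a non-overlapping grid")
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    offsets: dict[str, int] = {}
    off = 0
    for chrom, clen in grid.chrom_lengths.items():
        offsets[chrom] = off
        off += -(-clen // grid.size)
    for s in sites:
        chrom = s.interval.chrom
        if chrom not in offsets:
            continue
        if not (0 <= s.interval.start < grid.chrom_lengths[chrom]):
            continue
        counts[offsets[chrom] + s.interval.start // grid.size] += 1
    return counts


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile: value at 1-based index ceil(q*n) of
    the sorted sample."""
    v = np.sort(np.asarray(values))
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(q * n))
    return float(v[rank - 1])


def detect_hotspots(
    counts: np.ndarray, cfg: HotspotConfig | None = None
) -> tuple[np.ndarray, float]:
    """Flag windows whose SV count reaches the nearest-rank count quantile.

    Returns (boolean flags aligned with the grid, threshold used).  Windows
    with count >= threshold are hotspots.
    """
    cfg = cfg or HotspotConfig()
    counts = np.asarray(counts)
    if len(counts) < 20:
        warn_once(f"only {len(counts)} windows; the quantile threshold is unstable")
    threshold = nearest_rank_quantile(counts, cfg.count_quantile)
    flags = counts >= threshold
    if flags.all():
        warn_once("degenerate count distribution: every window reaches the threshold")
    return flags, threshold


def hotspot_dominance(
    window_labels: Mapping[int, Sequence[str]],
    cfg: HotspotConfig | None = None,
) -> dict[int, str]:
    """Dominant mechanism per hotspot: the label forming more than
    ``dominance_fraction`` of the window's SVs, else ``mixed``."""
    cfg = cfg or HotspotConfig()
    out = {}
    for w, labels in window_labels.items():
        labels = [l for l in labels if l != "NA"]
        if not labels:
            raise ValueError(f"hotspot window {w} has no labelled SVs")
        counts = pd.Series(labels).value_counts()
        top = counts.index[0]
        out[w] = top if counts.iloc[0] / len(labels) > cfg.dominance_fraction else "mixed"
    return out


def mechanism_enrichment_fisher(
    mech_in: int, other_in: int, mech_out: int, other_out: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of mechanism-by-hotspot association
    on the 2x2 table [[mech_in, other_in], [mech_out, other_out]].

    A zero margin carries no information: p = 1 and the odds ratio is NA.
    """
    table = np.array([[mech_in, other_in], [mech_out, other_out]])
    if (table < 0).any():
        raise ValueError("table entries must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def dominance_anova(per_hotspot_fractions: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA across mechanisms of per-hotspot mechanism fractions.

    Input: hotspots x mechanisms frame of composition fractions.  Tests
    whether mean composition differs among mechanisms (a dominant mechanism
    shows as a high-mean column).
    """
    groups = [per_hotspot_fractions[c].dropna().to_numpy()
              for c in per_hotspot_fractions.columns]
    groups = [g for g in groups if len(g) > 1]
    if len(groups) < 2:
        raise ValueError("need at least two mechanisms with >=2 hotspots each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def hotspot_scan(
    sites: Sequence[SVSite],
    labels: pd.DataFrame,
    grid: WindowGrid,
    cfg: HotspotConfig | None = None,
) -> pd.DataFrame:
    """End-to-end hotspot table: window, count, hotspot flag, dominant
    mechanism (for hotspots with labelled deletions)."""
    cfg = cfg or HotspotConfig()
    counts = window_sv_counts(sites, grid)
    flags, threshold = detect_hotspots(counts, cfg)
    label_of = dict(zip(labels["site_id"], labels["mechanism"]))
    window_labels: dict[int, list[str]] = {}
    offsets: dict[str, int] = {}
    off = 0
    for chrom, clen in grid.chrom_lengths.items():
        offsets[chrom] = off
        off += -(-clen // grid.size)
    for s in sites:
        chrom = s.interval.chrom
        if chrom not in offsets or s.site_id not in label_of:
            continue
        if not (0 <= s.interval.start < grid.chrom_lengths[chrom]):
            continue
        w = offsets[chrom] + s.interval.start // grid.size
        if flags[w]:
            window_labels.setdefault(w, []).append(label_of[s.site_id])
    dominant = hotspot_dominance(
        {w: ls for w, ls in window_labels.items() if ls}, cfg
    ) if window_labels else {}
    frame = grid.frame()
    frame["count"] = counts
    frame["hotspot"] = flags
    frame["threshold"] = threshold
    frame["dominant"] = [dominant.get(i, "") for i in range(grid.n_windows)]
    return frame
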