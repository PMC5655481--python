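"""Top-differentiated deletion loci, LD anchoring to SNPs, DEL-DC clusters,
TSS grouping, and the within-vs-total Fst-dispersion D statistic.

The cluster construction follows the deletion-anchored definition: top-Fst
deletions seed clusters with their own intervals and with the spans to any
top-Fst SNPs in high LD (r^2 > 0.9) with them; overlapping or touching seed
regions merge into deletion-anchored differentiated clusters (DEL-DC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnnotationSet,
    GenomicInterval,
    GenotypeMatrix,
    merge_intervals,
)
from .mechanism import nearest_rank_quantile
from .popstats import PermutationResult, ld_r2

log = logging.getLogger("svpopdiff")


@dataclass
class DelDcCluster:
    interval: GenomicInterval
    member_deletions: list[str]
    anchored_snps: int

    @property
    def size(self) -> int:
        return self.interval.length


def select_top_loci(
    sites: pd.DataFrame,
    fst: np.ndarray,
    p: np.ndarray,
    fraction: float = 0.05,
    alpha: float = 0.001,
) -> tuple[pd.DataFrame, float]:
    """Loci surpassing the top-``fraction`` Fst level with permutation
    p < ``alpha``.

    The threshold is the nearest-rank (1 - fraction) empirical quantile of
    all site Fst values (NaN excluded); a locus passes when fst >= threshold
    AND p < alpha.  Returns (frame with fst/p/passes columns, threshold).
    """
    fst = np.asarray(fst, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(fst) != len(sites) or len(p) != len(sites):
        raise ValueError("fst and p must align with the sites frame")
    usable = fst[~np.isnan(fst)]
    if len(usable) == 0:
        raise ValueError("no usable Fst values")
    threshold = nearest_rank_quantile(usable, 1.0 - fraction)
    with np.errstate(invalid="ignore"):
        passes = (fst >= threshold) & (p < alpha)
    out = sites.copy().reset_index(drop=True)
    out["fst"] = fst
    out["p"] = p
    out["passes"] = np.where(np.isnan(fst) | np.isnan(p), False, passes)
    return out, threshold


def _interval_point_distance(start: int, end: int, pos: int) -> int:
    """bp distance from a half-open interval to a point (0 when inside)."""
    return max(start - pos, pos - (end - 1), 0)


def anchor_snps(
    deletions: pd.DataFrame,
    snps: pd.DataFrame,
    del_matrix: GenotypeMatrix,
    snp_matrix: GenotypeMatrix,
    r2_min: float = 0.9,
    max_dist: int = 1_000_000,
) -> pd.DataFrame:
    """Pairs of passing deletions and passing SNPs on the same chromosome,
    within ``max_dist`` of the deletion interval, with r^2 strictly above
    ``r2_min``.

    Both matrices must share the same sample ordering.
    """
    if del_matrix.samples != snp_matrix.samples:
        raise ValueError("deletion and SNP matrices must share sample order")
    del_pos = {
        sid: j for j, sid in enumerate(del_matrix.sites["site_id"])
    }
    snp_pos = {
        sid: j for j, sid in enumerate(snp_matrix.sites["site_id"])
    }
    rows = []
    for _, drow in deletions.iterrows():
        dj = del_pos[drow["site_id"]]
        for _, srow in snps.iterrows():
            if srow["chrom"] != drow["chrom"]:
                continue
            dist = _interval_point_distance(
                int(drow["start"]), int(drow["end"]), int(srow["start"])
            )
            if dist > max_dist:
                continue
            sj = snp_pos[srow["site_id"]]
            r2 = ld_r2(del_matrix.dosage[:, dj], snp_matrix.dosage[:, sj])
            if not np.isnan(r2) and r2 > r2_min:
                rows.append(
                    (drow["site_id"], srow["site_id"], drow["chrom"],
                     int(srow["start"]), dist, r2)
                )
    return pd.DataFrame(
        rows, columns=["del_id", "snp_id", "chrom", "snp_pos", "dist", "r2"]
    )


def low_ld_deletions(
    deletions: pd.DataFrame,
    snp_matrix: GenotypeMatrix,
    del_matrix: GenotypeMatrix,
    r2_cut: float = 0.6,
    max_dist: int = 1_000_000,
) -> pd.DataFrame:
    """Deletions whose maximum r^2 with any SNP within ``max_dist`` is below
    ``r2_cut`` — loci carrying differentiation signal no nearby SNP tags.

    A deletion with no SNP in range is returned with max_r2 = NaN (vacuous
    maximum; declared).
    """
    if del_matrix.samples != snp_matrix.samples:
        raise ValueError("deletion and SNP matrices must share sample order")
    del_pos = {sid: j for j, sid in enumerate(del_matrix.sites["site_id"])}
    s_chrom = snp_matrix.sites["chrom"].to_numpy()
    s_start = snp_matrix.sites["start"].to_numpy()
    rows = []
    for _, drow in deletions.iterrows():
        dj = del_pos[drow["site_id"]]
        near = np.flatnonzero(
            (s_chrom == drow["chrom"])
            & (s_start >= int(drow["start"]) - max_dist)
            & (s_start < int(drow["end"]) + max_dist)
        )
        best = float("nan")
        for sj in near:
            if _interval_point_distance(
                int(drow["start"]), int(drow["end"]), int(s_start[sj])
            ) > max_dist:
                continue
            r2 = ld_r2(del_matrix.dosage[:, dj], snp_matrix.dosage[:, sj])
            if not np.isnan(r2) and (np.isnan(best) or r2 > best):
                best = r2
        if np.isnan(best) or best < r2_cut:
            rows.append((drow["site_id"], drow["chrom"], best))
    return pd.DataFrame(rows, columns=["del_id", "chrom", "max_r2"])


def max_nearby_r2(
    deletions: pd.DataFrame,
    snp_matrix: GenotypeMatrix,
    del_matrix: GenotypeMatrix,
    max_dist: int = 1_000_000,
) -> np.ndarray:
    """Per passing deletion, the maximum r^2 with any SNP within range."""
    del_pos = {sid: j for j, sid in enumerate(del_matrix.sites["site_id"])}
    s_chrom = snp_matrix.sites["chrom"].to_numpy()
    s_start = snp_matrix.sites["start"].to_numpy()
    out = np.full(len(deletions), np.nan)
    for i, (_, drow) in enumerate(deletions.iterrows()):
        dj = del_pos[drow["site_id"]]
        near = np.flatnonzero(
            (s_chrom == drow["chrom"])
            & (s_start >= int(drow["start"]) - max_dist)
            & (s_start < int(drow["end"]) + max_dist)
        )
        for sj in near:
            r2 = ld_r2(del_matrix.dosage[:, dj], snp_matrix.dosage[:, sj])
            if not np.isnan(r2) and (np.isnan(out[i]) or r2 > out[i]):
                out[i] = r2
    return out


def build_del_dc(
    anchored: pd.DataFrame,
    passing_deletions: pd.DataFrame,
) -> list[DelDcCluster]:
    """Merge anchored deletion-SNP spans and passing-deletion intervals into
    disjoint DEL-DC clusters.

    Seeds: each passing deletion's own interval, plus for every anchored
    (deletion, SNP) pair the span from the deletion to the SNP position.
    Overlapping or bookended seeds merge; SNP-only regions never seed a
    cluster on their own (deletion-anchored definition).
    """
    del_by_id = {
        row["site_id"]: (row["chrom"], int(row["start"]), int(row["end"]))
        for _, row in passing_deletions.iterrows()
    }
    seeds: list[GenomicInterval] = [
        GenomicInterval(c, s, e) for c, s, e in del_by_id.values()
    ]
    for _, pair in anchored.iterrows():
        c, s, e = del_by_id[pair["del_id"]]
        pos = int(pair["snp_pos"])
        seeds.append(
            GenomicInterval(c, min(s, pos), max(e, pos + 1))
        )
    clusters = []
    for iv in merge_intervals(seeds):
        members = [
            sid
            for sid, (c, s, e) in del_by_id.items()
            if c == iv.chrom and s < iv.end and e > iv.start
        ]
        n_snps = int(
            (
                (anchored["chrom"] == iv.chrom)
                & (anchored["snp_pos"] >= iv.start)
                & (anchored["snp_pos"] < iv.end)
            ).sum()
        ) if len(anchored) else 0
        clusters.append(DelDcCluster(iv, sorted(members), n_snps))
    return clusters


def del_dc_frame(clusters: Sequence[DelDcCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.interval.chrom,
                c.interval.start,
                c.interval.end,
                c.size,
                len(c.member_deletions),
                ",".join(c.member_deletions),
                c.anchored_snps,
            )
            for c in clusters
        ],
        columns=[
            "chrom", "start", "end", "size",
            "n_deletions", "deletions", "n_anchored_snps",
        ],
    )


def associate_genes(
    loci: pd.DataFrame,
    annotations: AnnotationSet,
    tss_max_dist: int = 200_000,
) -> pd.DataFrame:
    """Locus-to-gene links: a locus links to a gene when it overlaps one of
    the gene's transcripts OR lies within ``tss_max_dist`` bp of a TSS.
    Both criteria may fire; duplicate links collapse."""
    tx = annotations["transcripts"]
    links: set[tuple[str, str, str]] = set()
    for _, row in loci.iterrows():
        sub = tx[tx["chrom"] == row["chrom"]]
        lo, hi = int(row["start"]), int(row["end"])
        overlap = (sub["start"] < hi) & (sub["end"] > lo)
        for _, t in sub[overlap].iterrows():
            links.add((row["site_id"], t["gene_id"], "overlap"))
        dist = np.array(
            [_interval_point_distance(lo, hi, int(t)) for t in sub["tss"]]
        )
        for _, t in sub[dist <= tss_max_dist].iterrows():
            links.add((row["site_id"], t["gene_id"], "tss"))
    frame = pd.DataFrame(sorted(links), columns=["site_id", "gene_id", "criterion"])
    # a locus-gene pair satisfying both criteria is reported once, as overlap
    frame = (
        frame.sort_values(["site_id", "gene_id", "criterion"])
        .drop_duplicates(["site_id", "gene_id"], keep="first")
        .reset_index(drop=True)
    )
    return frame


def tss_grouping(
    deletions: pd.DataFrame,
    annotations: AnnotationSet,
    near_tss_bp: int = 50_000,
) -> pd.Series:
    """Partition deletions into INTRON / C50 / D50 regulatory-distance groups.

    INTRON (overlaps an annotated intron) takes precedence; otherwise C50
    when the distance to the nearest TSS is <= ``near_tss_bp`` (boundary
    inclusive), else D50.  Every deletion receives exactly one label.
    """
    tx = annotations["transcripts"]
    introns = annotations.get("introns")
    labels = []
    for _, row in deletions.iterrows():
        lo, hi = int(row["start"]), int(row["end"])
        if introns is not None:
            sub = introns[introns["chrom"] == row["chrom"]]
            if ((sub["start"] < hi) & (sub["end"] > lo)).any():
                labels.append("INTRON")
                continue
        sub = tx[tx["chrom"] == row["chrom"]]
        if len(sub):
            dist = min(
                _interval_point_distance(lo, hi, int(t)) for t in sub["tss"]
            )
        else:
            dist = np.inf
        labels.append("C50" if dist <= near_tss_bp else "D50")
    return pd.Series(labels, index=deletions.index, name="tss_group")


def d_statistic_from_variances(
    var_total: float,
    var_a: float,
    var_b: float,
    n_a: int,
    n_b: int,
) -> float:
    """Fst-dispersion D from pre-computed variances.

    D = [sigma_T^2 - (sigma_A^2/n_A + sigma_B^2/n_B)/(n_A + n_B)] / sigma_T^2

    where sigma_T^2 is the variance of the pooled Fst values and sigma_A^2,
    sigma_B^2 the within-group variances; D = 1 when both within-group
    variances vanish, and decreases as they grow.  NaN when sigma_T^2 = 0.
    """
    if min(var_total, var_a, var_b) < 0:
        raise ValueError("variances must be nonnegative")
    if var_total == 0:
        return float("nan")
    penalty = (var_a / n_a + var_b / n_b) / (n_a + n_b)
    return (var_total - penalty) / var_total


def d_statistic(
    fst_a: Sequence[float],
    fst_b: Sequence[float],
    n_a: int | None = None,
    n_b: int | None = None,
) -> float:
    """D from the two per-comparison Fst value sets.

    Variances are population variances (ddof=0); group sizes default to the
    lengths of the value sets.
    """
    a = np.asarray(fst_a, dtype=float)
    b = np.asarray(fst_b, dtype=float)
    pooled = np.concatenate([a, b])
    return d_statistic_from_variances(
        float(np.var(pooled)),
        float(np.var(a)),
        float(np.var(b)),
        n_a if n_a is not None else len(a),
        n_b if n_b is not None else len(b),
    )


def d_statistic_permutation(
    fst_a: Sequence[float],
    fst_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation p for D: shuffle the pooled Fst values between the two
    groups (sizes kept), count permuted D >= observed."""
    a = np.asarray(fst_a, dtype=float)
    b = np.asarray(fst_b, dtype=float)
    observed = d_statistic(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = d_statistic(perm[: len(a)], perm[len(a):])
        if not np.isnan(d) and d >= observed:
            n_exceed += 1
    return PermutationResult(observed, n_perm, n_exceed)


def chi2_ld_vs_differentiation(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) on the 2x2
    high-LD x high-differentiation contingency table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square is undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def ld_differentiation_table(
    passing: pd.DataFrame,
    max_r2: np.ndarray,
    r2_high: float = 0.9,
) -> np.ndarray:
    """Dichotomize passing loci into the 2x2 LD-by-differentiation table.

    'higher LD' = max nearby SNP r^2 > ``r2_high``; 'more significantly
    differentiated' = Fst at or above the median of the passing loci.
    Both cuts are configuration keys, not claims about the underlying data.
    """
    fst = passing["fst"].to_numpy(dtype=float)
    high_diff = fst >= np.median(fst)
    with np.errstate(invalid="ignore"):
        high_ld = np.where(np.isnan(max_r2), False, max_r2 > r2_high)
    return np.array(
        [
            [int((high_diff & high_ld).sum()), int((high_diff & ~high_ld).sum())],
            [int((~high_diff & high_ld).sum()), int((~high_diff & ~high_ld).sum())],
        ]
    )
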