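"""Population-genetic statistics on diploid dosage matrices.

Implements allele frequencies, observed heterozygosity, dosage-correlation
LD (r-squared), genotype PCA, the Weir & Cockerham (1984) two-population
Fst variance-components estimator with a group-label permutation null,
Tajima's D on variant windows, and group allele-sharing classification.

Conventions, declared once:

* missing genotypes (-1) are excluded pairwise for frequency, heterozygosity,
  LD, and Fst; they are mean-imputed only for PCA;
* r-squared is the squared Pearson correlation of diploid dosages (composite
  LD) — phase-free and deterministic, which differs slightly from EM-based
  haplotype r^2 on unphased data;
* Tajima's D treats each diploid as two chromosomes (n = 2 x samples) and
  computes per-site pairwise diversity from the non-missing allele counts of
  that site;
* the permutation empirical p is always (n_exceed + 1)/(n_perm + 1), where
  n_exceed counts permuted statistics >= the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PopulationPanel, WindowGrid, make_windows

log = logging.getLogger("svpopdiff")


@dataclass
class PermutationResult:
    observed: float
    n_perm: int
    n_exceed: int

    @property
    def p(self) -> float:
        return (self.n_exceed + 1) / (self.n_perm + 1)


@dataclass
class TajimaWindow:
    chrom: str
    start: int
    end: int
    n_sites: int
    S: int
    pi: float
    D: float  # NaN when S == 0


# ---------------------------------------------------------------------------
# frequencies and heterozygosity


def allele_frequencies(dosage: np.ndarray, sample_idx: np.ndarray | None = None) -> np.ndarray:
    """Per-site alternate-allele frequency: sum(dosage) / (2 x non-missing).

    All-missing sites return NaN.
    """
    d = dosage if sample_idx is None else dosage[sample_idx, :]
    nonmiss = d >= 0
    n = nonmiss.sum(axis=0)
    total = np.where(nonmiss, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, total / (2.0 * n), np.nan)


def observed_heterozygosity(
    dosage: np.ndarray, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Per-site observed heterozygote fraction among non-missing samples."""
    d = dosage if sample_idx is None else dosage[sample_idx, :]
    nonmiss = d >= 0
    n = nonmiss.sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, het / n, np.nan)


def group_heterozygosity(
    matrix: GenotypeMatrix, panel: PopulationPanel
) -> pd.DataFrame:
    """Per-breed per-site heterozygosity with a log10 reporting column.

    Monomorphic (het = 0) sites map to NaN on the log scale; this is the
    declared convention, logged once per run.
    """
    rows = []
    for breed in sorted(panel.frame["breed"].unique()):
        samples = panel.frame.loc[panel.frame["breed"] == breed, "sample"]
        idx = np.array(
            [matrix.samples.index(s) for s in samples if s in matrix.samples],
            dtype=np.intp,
        )
        if len(idx) == 0:
            continue
        het = observed_heterozygosity(matrix.dosage, idx)
        for j, h in enumerate(het):
            rows.append((breed, matrix.sites.iloc[j]["site_id"], h))
    frame = pd.DataFrame(rows, columns=["breed", "site_id", "het"])
    n_zero = int((frame["het"] == 0).sum())
    if n_zero:
        log.info("log10 heterozygosity: %d zero-het entries reported as NaN", n_zero)
    with np.errstate(divide="ignore"):
        frame["log10_het"] = np.where(
            frame["het"] > 0, np.log10(frame["het"]), np.nan
        )
    return frame


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst


def wc_fst_components(
    dosage: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components for two
    populations of diploids.

    Returns arrays (a, b, c): among-population, among-individual-within-
    population, and within-individual components.  Sites with fewer than two
    non-missing genotypes in either group are NaN (skipped downstream with a
    count).  The per-site estimator is a/(a+b+c); multi-site estimates use
    the ratio of sums.
    """
    r = 2.0
    comps = []
    for idx in (idx_a, idx_b):
        d = dosage[idx, :]
        nonmiss = d >= 0
        n_i = nonmiss.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(nonmiss, d, 0).sum(axis=0) / (2.0 * n_i)
            h_i = (d == 1).sum(axis=0) / n_i
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def site_fst(dosage: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Per-site Fst a/(a+b+c); NaN where components are unavailable or the
    site is monomorphic across both groups (zero denominator)."""
    a, b, c = wc_fst_components(dosage, idx_a, idx_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.abs(denom) > 0, a / denom, np.nan)


def weighted_fst(dosage: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    """Ratio-of-sums (weighted) Fst over all usable sites."""
    a, b, c = wc_fst_components(dosage, idx_a, idx_b)
    denom = np.nansum(a + b + c)
    if denom == 0 or np.isnan(denom):
        return float("nan")
    return float(np.nansum(a) / denom)


def windowed_fst(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    group_a: str,
    group_b: str,
    grid: WindowGrid | None = None,
    window_size: int = 1_000_000,
) -> pd.DataFrame:
    """Weighted Fst per genomic window (default non-overlapping 1 Mb).

    The raw ratio-of-sums value is kept (it may be slightly negative); a
    clipped-to-[0,1] column is provided for reporting.
    """
    gi = panel.group_indices(matrix.samples)
    idx_a, idx_b = gi[group_a], gi[group_b]
    if grid is None:
        lengths = (
            matrix.sites.groupby("chrom")["end"].max().astype(int) + 1
        ).to_dict()
        grid = make_windows(lengths, window_size)
    a, b, c = wc_fst_components(matrix.dosage, idx_a, idx_b)
    starts = matrix.sites["start"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    rows = []
    for w in grid.windows:
        in_w = (chroms == w.chrom) & (starts >= w.start) & (starts < w.end)
        aw, bw, cw = a[in_w], b[in_w], c[in_w]
        usable = ~np.isnan(aw)
        n_sites = int(usable.sum())
        if n_sites == 0:
            fst = float("nan")
        else:
            denom = np.nansum(aw + bw + cw)
            fst = float(np.nansum(aw) / denom) if denom != 0 else float("nan")
        rows.append((w.chrom, w.start, w.end, n_sites, fst))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "fst"])
    frame["fst_clipped"] = frame["fst"].clip(0.0, 1.0)
    return frame


def permutation_fst_p(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    group_a: str,
    group_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: Callable[[np.ndarray, np.ndarray, np.ndarray], float] | None = None,
) -> PermutationResult:
    """Group-label permutation test of the (default genome-wide weighted)
    Fst between two groups.

    Labels are shuffled over the pooled samples of the two groups with the
    group sizes kept fixed; ``n_exceed`` counts permuted statistics greater
    than or equal to the observed one, and p = (n_exceed + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat = statistic or weighted_fst
    gi = panel.group_indices(matrix.samples)
    idx_a, idx_b = gi[group_a], gi[group_b]
    observed = stat(matrix.dosage, idx_a, idx_b)
    rng = np.random.default_rng(seed)
    pool = np.concatenate([idx_a, idx_b])
    n_a = len(idx_a)
    n_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        if stat(matrix.dosage, perm[:n_a], perm[n_a:]) >= observed:
            n_exceed += 1
    return PermutationResult(observed, n_perm, n_exceed)


def persite_permutation_p(
    dosage: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Fst with per-site permutation empirical p-values.

    Observed and permuted replicates are computed over the same site set;
    per site, p = (#{permuted fst >= observed} + 1)/(n_perm + 1).  NaN
    observed values get p = NaN.
    """
    observed = site_fst(dosage, idx_a, idx_b)
    rng = np.random.default_rng(seed)
    pool = np.concatenate([idx_a, idx_b])
    n_a = len(idx_a)
    n_exceed = np.zeros(len(observed), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        f = site_fst(dosage, perm[:n_a], perm[n_a:])
        with np.errstate(invalid="ignore"):
            n_exceed += np.where(np.isnan(f), 0, (f >= observed)).astype(np.int64)
    p = (n_exceed + 1) / (n_perm + 1)
    p = np.where(np.isnan(observed), np.nan, p)
    return observed, p


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int) -> tuple[float, float, float, float]:
    """(a1, a2, e1, e2) for sample size n chromosomes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, e1, e2


def tajimas_d(
    dosage: np.ndarray, sample_idx: np.ndarray | None = None
) -> tuple[int, float, float]:
    """Tajima's D over the sites of one window.

    Returns (S, pi, D).  n for the normalizing constants is 2 x samples
    (each diploid contributes two chromosomes); per-site pairwise diversity
    uses that site's non-missing allele counts: pi_site = 2k(m-k)/(m(m-1))
    with m non-missing chromosomes and k alternate alleles.  S counts sites
    polymorphic among the non-missing genotypes.  D is NaN when S = 0.
    """
    d = dosage if sample_idx is None else dosage[sample_idx, :]
    n = 2 * d.shape[0]
    if n < 4:
        raise ValueError("need at least 2 diploid samples (4 chromosomes)")
    nonmiss = d >= 0
    m = 2.0 * nonmiss.sum(axis=0)
    k = np.where(nonmiss, d, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        poly = (k > 0) & (k < m)
        pi_site = np.where(
            (m > 1) & poly, 2.0 * k * (m - k) / (m * (m - 1.0)), 0.0
        )
    S = int(poly.sum())
    pi = float(pi_site.sum())
    if S == 0:
        return 0, 0.0, float("nan")
    a1, _, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    D = (pi - S / a1) / np.sqrt(var)
    return S, pi, float(D)


def sliding_tajimas_d(
    matrix: GenotypeMatrix,
    sample_idx: np.ndarray | None = None,
    mode: str = "variants",
    window: int = 20,
    step: int = 10,
    bp_window: int = 1_000_000,
) -> list[TajimaWindow]:
    """Tajima's D in sliding windows, per chromosome.

    ``variants`` mode slides over variant indices (window of 20 deletions,
    step 10 by default).  Full windows start at multiples of the step; a
    trailing partial window is kept only when it holds at least ``step``
    variants AND extends past the coverage of the last full window (so 20
    variants yield exactly one window, and 40 yield exactly the three full
    ones).  A chromosome with fewer variants than one window yields a single
    partial window with a warning.  ``bp`` mode delegates to the 1 Mb
    non-overlapping grid.
    """
    if mode not in ("variants", "bp"):
        raise ValueError(f"mode must be 'variants' or 'bp', got {mode!r}")
    out: list[TajimaWindow] = []
    for chrom in matrix.sites["chrom"].unique():
        idx = matrix.sites_on(chrom)
        sub = matrix.dosage[:, idx]
        starts = matrix.sites["start"].to_numpy()[idx]
        ends = matrix.sites["end"].to_numpy()[idx]
        if mode == "bp":
            length = int(ends.max()) + 1
            grid = make_windows({chrom: length}, bp_window)
            for w in grid.windows:
                in_w = (starts >= w.start) & (starts < w.end)
                if not in_w.any():
                    continue
                S, pi, D = tajimas_d(sub[:, in_w], sample_idx)
                out.append(TajimaWindow(chrom, w.start, w.end, int(in_w.sum()), S, pi, D))
            continue
        n_var = len(idx)
        if n_var == 0:
            continue
        if n_var < window:
            log.warning(
                "chromosome %s has %d < %d variants; single partial window",
                chrom, n_var, window,
            )
            spans = [(0, n_var)]
        else:
            spans = []
            last_full = 0
            k = 0
            while k * step + window <= n_var:
                spans.append((k * step, k * step + window))
                last_full = k * step
                k += 1
            trail_start = last_full + step
            if n_var > last_full + window and n_var - trail_start >= step:
                spans.append((trail_start, n_var))
        for lo, hi in spans:
            S, pi, D = tajimas_d(sub[:, lo:hi], sample_idx)
            out.append(
                TajimaWindow(
                    chrom, int(starts[lo]), int(ends[hi - 1]), hi - lo, S, pi, D
                )
            )
    return out


def tajima_frame(windows: Sequence[TajimaWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.chrom, w.start, w.end, w.n_sites, w.S, w.pi, w.D) for w in windows],
        columns=["chrom", "start", "end", "n_sites", "S", "pi", "D"],
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-
    complete samples; NaN when either site has zero variance or fewer than
    two complete pairs."""
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return float("nan")
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    vx, vy = xv.var(), yv.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((xv - xv.mean()) * (yv - yv.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_pairs(
    matrix: GenotypeMatrix,
    max_dist: int = 1_000_000,
    min_r2_report: float | None = None,
) -> pd.DataFrame:
    """All same-chromosome site pairs within ``max_dist`` with their r^2.

    ``min_r2_report`` filters only this pair dump (mirroring LD-tool report
    thresholds); binned decay means always use every pair.
    """
    chroms = matrix.sites["chrom"].to_numpy()
    starts = matrix.sites["start"].to_numpy()
    rows = []
    for j in range(matrix.n_sites):
        for k in range(j + 1, matrix.n_sites):
            if chroms[k] != chroms[j]:
                continue
            dist = int(abs(starts[k] - starts[j]))
            if dist > max_dist:
                if starts[k] > starts[j]:  # sites sorted: no closer k beyond
                    break
                continue
            r2 = ld_r2(matrix.dosage[:, j], matrix.dosage[:, k])
            rows.append((j, k, dist, r2))
    frame = pd.DataFrame(rows, columns=["site_i", "site_j", "dist", "r2"])
    if min_r2_report is not None:
        frame = frame[frame["r2"] >= min_r2_report].reset_index(drop=True)
    return frame


def ld_decay_profile(
    matrix: GenotypeMatrix,
    max_dist: int = 1_000_000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean r^2 per distance bin over all same-chromosome pairs within
    ``max_dist``."""
    pairs = ld_pairs(matrix, max_dist=max_dist)
    edges = np.linspace(0, max_dist, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = pairs[(pairs["dist"] >= lo) & (pairs["dist"] < hi)]
        rows.append(
            (int(lo), int(hi), len(sel), float(sel["r2"].mean()) if len(sel) else np.nan)
        )
    return pd.DataFrame(rows, columns=["dist_lo", "dist_hi", "n_pairs", "mean_r2"])


# ---------------------------------------------------------------------------
# PCA


def pca(
    matrix: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA: centre dosages by 2p, scale by sqrt(2p(1-p)), impute
    missing to the site mean, eigendecompose the sample covariance.

    Returns (coordinates: samples x k, eigenvalues: k, non-increasing).
    Monomorphic sites are dropped; fewer than two polymorphic sites is an
    error.
    """
    if matrix.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    d = matrix.dosage.astype(float)
    d[d < 0] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("PCA needs at least 2 polymorphic sites")
    d = d[:, poly]
    p = p[poly]
    mean = 2.0 * p
    d = np.where(np.isnan(d), mean, d)
    z = (d - mean) / np.sqrt(2.0 * p * (1.0 - p))
    cov = z @ z.T / z.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_components, len(vals))
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    return coords, vals


# ---------------------------------------------------------------------------
# group allele sharing


def group_allele_sharing(
    matrix: GenotypeMatrix, panel: PopulationPanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each site's alternate allele by group-presence pattern.

    An allele is present in a group when its group frequency is > 0 among
    non-missing samples.  Classes: ``specific:<g>`` (one group), ``shared-2``
    (two of three; generally, some but not all), ``shared-all``, ``absent``.
    All-missing sites are excluded and counted.  Per-genome specific-site
    rate = (#sites specific to g) / (#samples in g).
    """
    gi = panel.group_indices(matrix.samples)
    groups = panel.groups
    freqs = {g: allele_frequencies(matrix.dosage, gi[g]) for g in groups}
    classes = []
    n_excluded = 0
    for j in range(matrix.n_sites):
        present = [g for g in groups if not np.isnan(freqs[g][j]) and freqs[g][j] > 0]
        if all(np.isnan(freqs[g][j]) for g in groups):
            classes.append("all-missing")
            n_excluded += 1
        elif len(present) == 0:
            classes.append("absent")
        elif len(present) == 1:
            classes.append(f"specific:{present[0]}")
        elif len(present) == len(groups):
            classes.append("shared-all")
        else:
            classes.append(f"shared-{len(present)}")
    per_site = matrix.sites[["chrom", "start", "end", "site_id"]].copy()
    per_site["class"] = classes
    if n_excluded:
        log.info("allele sharing: %d all-missing sites excluded", n_excluded)
    rates = []
    for g in groups:
        n_specific = sum(c == f"specific:{g}" for c in classes)
        n_samples = len(gi[g])
        rates.append((g, n_specific, n_samples, n_specific / n_samples))
    per_group = pd.DataFrame(
        rates, columns=["group", "n_specific_sites", "n_samples", "per_genome_rate"]
    )
    return per_site, per_group
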