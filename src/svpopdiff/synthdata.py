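"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator states a world once and the tests measure it: structured
diploid populations at a configurable Balding–Nichols Fst, SNP and SV
dosage matrices with block LD, implanted differentiated deletion-SNP
systems, five-caller SV call sets with per-caller sensitivity, false-call
rate and breakpoint jitter, and random TE/VNTR/gene/LQLC annotation tracks.

Defaults emulate the original cohort at desk scale: 66 diploids in three
groups (20 + 18 + 28), a three-chromosome 24 Mb genome standing in for the
2.5 Gb pig assembly, SV counts scaled to roughly 1/100 of the survey's
merged set, and a deletion length mixture peaked near 300 bp (the SINE
hallmark).  Only coordinates and genotypes are simulated — no sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AnnotationSet,
    GenomicInterval,
    GenotypeMatrix,
    PopulationPanel,
    SVCall,
)

#: caller name -> (sensitivity, false calls per Mb per sample, jitter s.d. bp)
DEFAULT_CALLER_PROFILES: dict[str, tuple[float, float, float]] = {
    "delly": (0.90, 0.20, 3.0),
    "breakdancer": (0.85, 0.30, 25.0),
    "pindel": (0.90, 0.20, 2.0),
    "cnvnator": (0.70, 0.50, 50.0),
    "lumpy": (0.88, 0.20, 10.0),
}


@dataclass
class SimConfig:
    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 10_000_000, "2": 8_000_000, "3": 6_000_000}
    )
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NCPG": 20, "SCPG": 18, "TWPG": 28}
    )
    target_fst: float = 0.1
    n_snp: int = 2_000
    n_sv: dict[str, int] = field(
        default_factory=lambda: {"DEL": 500, "INV": 40, "DUP": 25}
    )
    ld_block_bp: int = 100_000
    ld_rho: float = 0.8
    n_implant: int = 20
    implant_delta: float = 0.8
    implant_pair_dist: int = 50_000
    missing_rate: float = 0.01
    caller_profiles: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CALLER_PROFILES)
    )
    te_per_mb: float = 60.0
    vntr_per_mb: float = 10.0
    genes_per_mb: float = 8.0
    lqlc_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not (0 <= self.target_fst < 1):
            raise ValueError("target_fst must be in [0, 1)")
        for name, v in (
            ("ld_rho", self.ld_rho),
            ("missing_rate", self.missing_rate),
            ("lqlc_fraction", self.lqlc_fraction),
        ):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for caller, (sens, fp, sd) in self.caller_profiles.items():
            if not (0 <= sens <= 1) or fp < 0 or sd < 0:
                raise ValueError(f"bad profile for caller {caller}")

    @property
    def genome_bp(self) -> int:
        return sum(self.chrom_lengths.values())


def _group_frequencies(
    rng: np.random.Generator, n_sites: int, n_groups: int, fst: float
) -> tuple[np.ndarray, np.ndarray]:
    """Balding–Nichols: ancestral p ~ U(0.05, 0.95); per-group frequencies
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F), or exactly p when F = 0."""
    p = rng.uniform(0.05, 0.95, size=n_sites)
    if fst == 0:
        return p, np.tile(p, (n_groups, 1))
    alpha = p * (1.0 - fst) / fst
    beta = (1.0 - p) * (1.0 - fst) / fst
    gp = rng.beta(alpha, beta, size=(n_groups, n_sites))
    return p, gp


def _dosages_with_ld(
    rng: np.random.Generator,
    group_freqs: np.ndarray,  # groups x sites
    group_sizes: list[int],
    positions: np.ndarray,
    chroms: np.ndarray,
    block_bp: int,
    rho: float,
) -> np.ndarray:
    """Diploid dosages ~ Binomial(2, p_group) with block LD.

    Each sample draws one latent uniform per LD block; per site, with
    probability rho the block latent is used instead of a fresh one, and the
    dosage is the Binomial(2, p) quantile at the latent.  Comonotone
    coupling within a block induces positive dosage correlation that decays
    with the mixing probability.
    """
    n_total = sum(group_sizes)
    n_sites = group_freqs.shape[1]
    block_key = pd.factorize(
        np.array([f"{c}:{pos // block_bp}" for c, pos in zip(chroms, positions)])
    )[0]
    n_blocks = block_key.max() + 1 if n_sites else 0
    dosage = np.zeros((n_total, n_sites), dtype=np.int16)
    row = 0
    for g, size in enumerate(group_sizes):
        p = group_freqs[g]  # per-site
        p0 = (1.0 - p) ** 2
        p01 = p0 + 2.0 * p * (1.0 - p)
        for _ in range(size):
            u_block = rng.uniform(size=n_blocks)
            u_fresh = rng.uniform(size=n_sites)
            use_block = rng.uniform(size=n_sites) < rho
            u = np.where(use_block, u_block[block_key], u_fresh)
            dosage[row] = (u > p0).astype(np.int16) + (u > p01).astype(np.int16)
            row += 1
    return dosage


def _sv_lengths(rng: np.random.Generator, svtype: str, n: int) -> np.ndarray:
    """Deletion lengths peak near 300 bp (SINE) with a long tail; inversions
    and duplications are longer and broader."""
    if svtype == "DEL":
        peak = rng.normal(300.0, 40.0, size=n)
        tail = np.exp(rng.uniform(np.log(50), np.log(60_000), size=n))
        lengths = np.where(rng.uniform(size=n) < 0.45, peak, tail)
    else:
        lengths = np.exp(rng.uniform(np.log(500), np.log(2_000_000), size=n))
    return np.clip(np.round(lengths), 50, 10_000_000).astype(np.int64)


def _random_sites(
    rng: np.random.Generator,
    cfg: SimConfig,
    svtype: str,
    n: int,
) -> pd.DataFrame:
    """Random site placement.  SV sites of one type emulate a merged call
    set, which is by construction separated at the merge criterion: a drawn
    interval reciprocally overlapping an accepted same-type interval by
    >= 0.5 is redrawn (bounded rejection sampling)."""
    from .core import GenomicInterval, reciprocal_overlap

    chrom_names = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    chroms = rng.choice(chrom_names, size=n, p=weights)
    lengths = _sv_lengths(rng, svtype, n) if svtype != "SNP" else np.ones(n, dtype=np.int64)
    starts = np.empty(n, dtype=np.int64)
    accepted: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_names}
    for i, (c, ln) in enumerate(zip(chroms, lengths)):
        clen = cfg.chrom_lengths[c]
        ln = min(int(ln), clen - 1)
        lengths[i] = ln
        for _ in range(50):
            s = int(rng.integers(0, clen - ln))
            iv = GenomicInterval(c, s, s + ln)
            if svtype == "SNP" or all(
                reciprocal_overlap(iv, prev) < 0.5 for prev in accepted[c]
            ):
                break
        starts[i] = s
        if svtype != "SNP":
            accepted[c].append(iv)
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "svtype": svtype,
            "site_id": [f"{svtype}_{i:06d}" for i in range(n)],
        }
    )
    return frame.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_panel(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, PopulationPanel, dict[str, pd.DataFrame]]:
    """Simulate the cohort: SNP matrix, SV matrix, panel, and truth tables.

    Implanted differentiated systems: ``n_implant`` deletions get the first
    two groups' frequencies pushed apart by ``implant_delta`` (clipped into
    [0.02, 0.98] with a warning when infeasible), and each gets a companion
    SNP within ``implant_pair_dist`` bp whose dosages copy the deletion's
    (2% per-genotype flip noise), creating the high-LD anchor structure.
    Truth tables list implanted deletion and SNP ids and the true SV sites.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_sizes)
    sizes = [cfg.group_sizes[g] for g in groups]
    samples = [f"{g}_{i:02d}" for g in groups for i in range(cfg.group_sizes[g])]
    breeds = [s.rsplit("_", 1)[0] for s in samples]
    panel = PopulationPanel(
        pd.DataFrame({"sample": samples, "breed": breeds, "group":
                      [g for g in groups for _ in range(cfg.group_sizes[g])]})
    )

    # SNP sites
    snp_sites = _random_sites(rng, cfg, "SNP", cfg.n_snp)
    _, snp_freqs = _group_frequencies(rng, cfg.n_snp, len(groups), cfg.target_fst)

    # SV sites, all types pooled into one matrix
    sv_frames = [
        _random_sites(rng, cfg, svtype, n) for svtype, n in cfg.n_sv.items() if n > 0
    ]
    sv_sites = (
        pd.concat(sv_frames, ignore_index=True)
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    n_sv_total = len(sv_sites)
    _, sv_freqs = _group_frequencies(rng, n_sv_total, len(groups), cfg.target_fst)

    # implant differentiated deletion loci (groups[0] vs groups[1])
    del_rows = np.flatnonzero((sv_sites["svtype"] == "DEL").to_numpy())
    n_implant = min(cfg.n_implant, len(del_rows))
    implant_idx = rng.choice(del_rows, size=n_implant, replace=False)
    clipped = 0
    for j in implant_idx:
        lo = 0.5 - cfg.implant_delta / 2.0
        hi = 0.5 + cfg.implant_delta / 2.0
        if lo < 0.02 or hi > 0.98:
            clipped += 1
        sv_freqs[0, j] = np.clip(hi, 0.02, 0.98)
        sv_freqs[1, j] = np.clip(lo, 0.02, 0.98)
    if clipped:
        import warnings

        warnings.warn(f"{clipped} implanted loci clipped to feasible frequencies")

    snp_dosage = _dosages_with_ld(
        rng, snp_freqs, sizes,
        snp_sites["start"].to_numpy(), snp_sites["chrom"].to_numpy(),
        cfg.ld_block_bp, cfg.ld_rho,
    )
    sv_dosage = _dosages_with_ld(
        rng, sv_freqs, sizes,
        sv_sites["start"].to_numpy(), sv_sites["chrom"].to_numpy(),
        cfg.ld_block_bp, cfg.ld_rho,
    )

    # companion SNPs copying implanted deletion dosages (high LD anchors)
    pair_rows = []
    extra_sites, extra_dosage = [], []
    for k, j in enumerate(implant_idx):
        site = sv_sites.iloc[j]
        clen = cfg.chrom_lengths[site["chrom"]]
        offset = int(rng.integers(500, cfg.implant_pair_dist))
        pos = min(max(0, int(site["start"]) - offset), clen - 2)
        snp_id = f"SNP_implant_{k:03d}"
        extra_sites.append((site["chrom"], pos, pos + 1, "SNP", snp_id))
        copied = sv_dosage[:, j].copy()
        flip = rng.uniform(size=len(copied)) < 0.02
        noise = rng.integers(0, 3, size=len(copied)).astype(np.int16)
        copied = np.where(flip, noise, copied)
        extra_dosage.append(copied)
        pair_rows.append((site["site_id"], snp_id))
    if extra_sites:
        snp_sites = pd.concat(
            [snp_sites, pd.DataFrame(extra_sites, columns=list(GenotypeMatrix.SITE_COLUMNS))],
            ignore_index=True,
        )
        snp_dosage = np.hstack([snp_dosage, np.column_stack(extra_dosage)])

    # missingness
    for dosage in (snp_dosage, sv_dosage):
        if cfg.missing_rate > 0:
            miss = rng.uniform(size=dosage.shape) < cfg.missing_rate
            dosage[miss] = -1

    snp_matrix = GenotypeMatrix(snp_sites, samples, snp_dosage)
    sv_matrix = GenotypeMatrix(sv_sites, samples, sv_dosage)
    truth = {
        "implanted_deletions": pd.DataFrame(
            {"site_id": sv_sites.loc[implant_idx, "site_id"].to_numpy()}
        ),
        "implanted_pairs": pd.DataFrame(pair_rows, columns=["del_id", "snp_id"]),
        "sv_sites": sv_sites.copy(),
    }
    return snp_matrix, sv_matrix, panel, truth


def simulate_caller_outputs(
    sv_matrix: GenotypeMatrix,
    cfg: SimConfig,
    eligible: dict[str, frozenset[str]] | None = None,
    seed: int | None = None,
) -> dict[str, list[SVCall]]:
    """Per-sample per-caller call lists from the true SV sites.

    A sample carries an SV when its dosage is >= 1.  Each eligible caller
    detects a carried SV with its sensitivity; detected breakpoints are
    jittered by rounded Normal(0, s.d.) noise (length floored at 50 bp).
    False calls are placed uniformly at the configured per-Mb rate with
    log-uniform lengths in [50 bp, 60 kb] and a random eligible type.
    """
    from .consensus import DEFAULT_CALLERS

    eligible = eligible or DEFAULT_CALLERS
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    caller_types: dict[str, list[str]] = {}
    for svtype, callers in eligible.items():
        for c in callers:
            caller_types.setdefault(c, []).append(svtype)

    chrom_names = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    genome_mb = cfg.genome_bp / 1e6

    out: dict[str, list[SVCall]] = {s: [] for s in sv_matrix.samples}
    sites = sv_matrix.sites
    for i, sample in enumerate(sv_matrix.samples):
        carried = np.flatnonzero(sv_matrix.dosage[i] >= 1)
        for j in carried:
            row = sites.iloc[j]
            svtype = row["svtype"]
            for caller in sorted(eligible.get(svtype, frozenset())):
                sens, _, jitter = cfg.caller_profiles[caller]
                if rng.uniform() >= sens:
                    continue
                if jitter > 0:
                    ds = int(round(rng.normal(0.0, jitter)))
                    de = int(round(rng.normal(0.0, jitter)))
                else:
                    ds = de = 0
                start = max(0, int(row["start"]) + ds)
                end = int(row["end"]) + de
                if end - start < 50:
                    end = start + 50
                clen = cfg.chrom_lengths[row["chrom"]]
                end = min(end, clen)
                start = min(start, end - 50)
                out[sample].append(
                    SVCall(
                        GenomicInterval(row["chrom"], max(0, start), end),
                        svtype, caller, sample,
                    )
                )
        # false calls
        for caller, (_, fp_per_mb, _) in sorted(cfg.caller_profiles.items()):
            n_fp = rng.poisson(fp_per_mb * genome_mb)
            for _ in range(n_fp):
                svtype = caller_types.get(caller, ["DEL"])
                svtype = svtype[rng.integers(0, len(svtype))]
                chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
                length = int(np.exp(rng.uniform(np.log(50), np.log(60_000))))
                clen = cfg.chrom_lengths[chrom]
                length = min(length, clen - 1)
                start = int(rng.integers(0, clen - length))
                out[sample].append(
                    SVCall(
                        GenomicInterval(chrom, start, start + length),
                        svtype, caller, sample,
                    )
                )
    return out


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom: str,
    clen: int,
    lengths: np.ndarray,
) -> list[tuple[int, int]]:
    """Place intervals uniformly and drop ones overlapping a prior keep."""
    starts = rng.integers(0, np.maximum(1, clen - lengths))
    order = np.argsort(starts)
    kept: list[tuple[int, int]] = []
    last_end = -1
    for i in order:
        s, e = int(starts[i]), int(starts[i] + lengths[i])
        if s > last_end and e <= clen:
            kept.append((s, e))
            last_end = e
    return kept


def simulate_annotations(cfg: SimConfig, seed: int | None = None) -> AnnotationSet:
    """Random annotation tracks: TE (length mixture peaked near 300 bp),
    VNTR, gene models with exon/intron structure and strand, LQLC mask.
    All tracks are sorted, non-overlapping within themselves, and inside
    chromosome bounds."""
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    ann = AnnotationSet()
    te_rows, vntr_rows, lqlc_rows = [], [], []
    tx_rows, intron_rows = [], []
    tx_counter = 0
    for chrom, clen in cfg.chrom_lengths.items():
        mb = clen / 1e6
        # TE: 80% tight SINE-like peak at 300 bp, 20% longer elements
        n_te = rng.poisson(cfg.te_per_mb * mb)
        if n_te:
            peak = rng.normal(300.0, 35.0, size=n_te)
            long_ = np.exp(rng.uniform(np.log(500), np.log(6_000), size=n_te))
            lens = np.where(rng.uniform(size=n_te) < 0.8, peak, long_)
            lens = np.clip(np.round(lens), 50, None).astype(np.int64)
            te_rows += [(chrom, s, e) for s, e in _place_nonoverlapping(rng, chrom, clen, lens)]
        n_vntr = rng.poisson(cfg.vntr_per_mb * mb)
        if n_vntr:
            lens = rng.integers(100, 2_000, size=n_vntr)
            vntr_rows += [(chrom, s, e) for s, e in _place_nonoverlapping(rng, chrom, clen, lens)]
        n_genes = rng.poisson(cfg.genes_per_mb * mb)
        if n_genes:
            lens = rng.integers(5_000, 80_000, size=n_genes)
            for s, e in _place_nonoverlapping(rng, chrom, clen, lens):
                strand = "+" if rng.uniform() < 0.5 else "-"
                tss = s if strand == "+" else e - 1
                tx_id = f"tx_{tx_counter:05d}"
                gene_id = f"gene_{tx_counter:05d}"
                tx_counter += 1
                tx_rows.append((chrom, s, e, strand, gene_id, tx_id, tss))
                n_exons = int(rng.integers(2, 9))
                cuts = np.sort(rng.choice(
                    np.arange(s + 1, e), size=2 * (n_exons - 1), replace=False
                ))
                bounds = [s, *cuts.tolist(), e]
                for k in range(n_exons - 1):
                    ilo, ihi = bounds[2 * k + 1], bounds[2 * k + 2]
                    if ihi > ilo:
                        intron_rows.append((chrom, ilo, ihi, tx_id))
        if cfg.lqlc_fraction > 0:
            target = cfg.lqlc_fraction * clen
            n_lqlc = max(1, int(target / 55_000))
            lens = rng.integers(10_000, 100_000, size=n_lqlc)
            lqlc_rows += [(chrom, s, e) for s, e in _place_nonoverlapping(rng, chrom, clen, lens)]
    if te_rows:
        ann.add("te", pd.DataFrame(te_rows, columns=["chrom", "start", "end"]))
    if vntr_rows:
        ann.add("vntr", pd.DataFrame(vntr_rows, columns=["chrom", "start", "end"]))
    if lqlc_rows:
        ann.add("lqlc", pd.DataFrame(lqlc_rows, columns=["chrom", "start", "end"]))
    if tx_rows:
        ann.add(
            "transcripts",
            pd.DataFrame(
                tx_rows,
                columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id", "tss"],
            ),
        )
    if intron_rows:
        ann.add(
            "introns",
            pd.DataFrame(intron_rows, columns=["chrom", "start", "end", "transcript_id"]),
        )
    return ann
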