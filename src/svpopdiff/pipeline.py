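"""Orchestrated run: consensus -> mechanisms/hotspots -> population
statistics -> differentiation, as one configured, logged, reproducible
pipeline over either simulated or file-based inputs.

Every stage is a pure function of (inputs, config, seed); the summary is a
deterministic JSON-able dict, and tabular outputs are TSV with a YAML
sidecar recording the configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import differentiation as diff
from . import mechanism as mech
from . import popstats as ps
from .core import GenotypeMatrix, make_windows
from .synthdata import SimConfig, simulate_annotations, simulate_caller_outputs, simulate_panel

log = logging.getLogger("svpopdiff")


@dataclass
class RunConfig:
    """Configuration for a full synthetic-cohort run."""

    sim: SimConfig
    caller: cns.CallerConfig = field(default_factory=cns.CallerConfig)
    qc: cns.QCConfig = field(default_factory=cns.QCConfig)
    hotspot: mech.HotspotConfig = field(default_factory=mech.HotspotConfig)
    window_bp: int = 1_000_000
    n_perm: int = 1_999
    top_fraction: float = 0.05
    alpha: float = 0.001
    anchor_r2: float = 0.9
    low_ld_r2: float = 0.6
    tss_near_bp: int = 50_000
    tss_assoc_bp: int = 200_000

    @property
    def seed(self) -> int:
        return self.sim.seed


def run_all(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage in order and return the summary bundle.

    Any stage failure raises with the stage name attached; when ``out_dir``
    is given, per-stage TSVs, the JSON summary, and a YAML config sidecar
    are written there.
    """
    summary: dict = {"seed": cfg.seed}
    tables: dict[str, pd.DataFrame] = {}
    stage = "simulate"
    t0 = time.time()
    try:
        snp_matrix, sv_matrix, panel, truth = simulate_panel(cfg.sim)
        annotations = simulate_annotations(cfg.sim)
        calls_by_sample = simulate_caller_outputs(sv_matrix, cfg.sim, cfg.caller.eligible)
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "consensus"
        t0 = time.time()
        all_calls = [c for calls in calls_by_sample.values() for c in calls]
        supported = cns.support_filter(cns.size_filter(all_calls, cfg.qc), cfg.caller)
        merged = cns.build_merged_set(supported, cfg.caller)
        genotyped_input = sv_matrix.to_sv_sites()
        genotyped_sites = cns.build_genotyped_set(merged, genotyped_input, cfg.caller)
        precise = cns.split_precise_set(merged, cfg.qc)
        geno_matrix = GenotypeMatrix.from_sv_sites(genotyped_sites, sv_matrix.samples)
        cfg.qc.lqlc_mask = cfg.qc.lqlc_mask or "lqlc"
        geno_matrix, filter_report = cns.apply_population_filters(
            geno_matrix, cfg.qc, annotations
        )
        tables["consensus_summary"] = cns.consensus_summary(merged, precise, genotyped_sites)
        summary["consensus"] = {
            "n_merged": len(merged),
            "n_precise": len(precise),
            "n_genotyped": len(genotyped_sites),
            "per_type": tables["consensus_summary"].to_dict("records"),
            "filter_report": filter_report,
        }
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "mechanism"
        t0 = time.time()
        precise_dels = [s for s in precise if s.svtype == "DEL"]
        labels = mech.classify_all(precise_dels, annotations, cfg=cfg.hotspot)
        tables["mechanisms"] = labels
        props = mech.mechanism_proportions(
            list(zip(labels["mechanism"], labels["length"]))
        )
        tables["mechanism_proportions"] = props
        starts = np.sort(labels["start"].to_numpy())
        if len(starts) >= 3:
            z, p_runs = mech.runs_test(mech.spacing_sequence(starts))
        else:
            z, p_runs = float("nan"), float("nan")
        grid = make_windows(cfg.sim.chrom_lengths, cfg.window_bp)
        hotspots = mech.hotspot_scan(precise_dels, labels, grid, cfg.hotspot)
        tables["hotspots"] = hotspots
        summary["mechanism"] = {
            "proportions": props.to_dict("records"),
            "runs_z": z,
            "runs_p": p_runs,
            "n_hotspots": int(hotspots["hotspot"].sum()),
            "hotspot_threshold": float(hotspots["threshold"].iloc[0]),
        }
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "popstats"
        t0 = time.time()
        groups = panel.groups
        ga, gb = groups[0], groups[1]
        het = ps.group_heterozygosity(geno_matrix, panel)
        tables["heterozygosity"] = het
        ld = ps.ld_decay_profile(geno_matrix, max_dist=cfg.window_bp)
        tables["ld_decay"] = ld
        coords, eigvals = ps.pca(geno_matrix)
        tables["pca"] = pd.DataFrame(
            {
                "sample": geno_matrix.samples,
                "group": [panel.group_of(s) for s in geno_matrix.samples],
                "PC1": coords[:, 0],
                "PC2": coords[:, 1],
            }
        )
        tajd = ps.tajima_frame(ps.sliding_tajimas_d(geno_matrix))
        tables["tajimas_d"] = tajd
        wfst = ps.windowed_fst(geno_matrix, panel, ga, gb, grid=grid)
        tables["windowed_fst"] = wfst
        perm = ps.permutation_fst_p(
            geno_matrix, panel, ga, gb, n_perm=cfg.n_perm, seed=cfg.seed + 11
        )
        per_site_class, per_group = ps.group_allele_sharing(geno_matrix, panel)
        tables["allele_sharing"] = per_group
        summary["popstats"] = {
            "groups_compared": [ga, gb],
            "genome_fst": perm.observed,
            "genome_fst_p": perm.p,
            "mean_het": float(np.nanmean(het["het"])),
            "tajimas_d_mean": float(np.nanmean(tajd["D"])),
            "eigenvalue_1": float(eigvals[0]),
            "allele_sharing": per_group.to_dict("records"),
        }
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "differentiation"
        t0 = time.time()
        gi = panel.group_indices(geno_matrix.samples)
        del_mask = (geno_matrix.sites["svtype"] == "DEL").to_numpy()
        del_matrix = geno_matrix.subset_sites(del_mask)
        d_fst, d_p = ps.persite_permutation_p(
            del_matrix.dosage, gi[ga], gi[gb], n_perm=cfg.n_perm, seed=cfg.seed + 13
        )
        del_loci, del_thresh = diff.select_top_loci(
            del_matrix.sites, d_fst, d_p, cfg.top_fraction, cfg.alpha
        )
        s_fst, s_p = ps.persite_permutation_p(
            snp_matrix.dosage, gi[ga], gi[gb], n_perm=cfg.n_perm, seed=cfg.seed + 17
        )
        snp_loci, snp_thresh = diff.select_top_loci(
            snp_matrix.sites, s_fst, s_p, cfg.top_fraction, cfg.alpha
        )
        passing_dels = del_loci[del_loci["passes"]]
        passing_snps = snp_loci[snp_loci["passes"]]
        anchored = diff.anchor_snps(
            passing_dels, passing_snps, del_matrix, snp_matrix,
            r2_min=cfg.anchor_r2, max_dist=cfg.window_bp,
        )
        clusters = diff.build_del_dc(anchored, passing_dels)
        tables["del_dc"] = diff.del_dc_frame(clusters)
        low_ld = diff.low_ld_deletions(
            passing_dels, snp_matrix, del_matrix,
            r2_cut=cfg.low_ld_r2, max_dist=cfg.window_bp,
        )
        genes = diff.associate_genes(passing_dels, annotations, cfg.tss_assoc_bp)
        tss_groups = diff.tss_grouping(passing_dels, annotations, cfg.tss_near_bp)
        tables["tss_groups"] = passing_dels.assign(tss_group=tss_groups.to_numpy())[
            ["site_id", "chrom", "start", "end", "fst", "p", "tss_group"]
        ]
        max_r2 = diff.max_nearby_r2(passing_dels, snp_matrix, del_matrix, cfg.window_bp)
        if len(passing_dels) >= 4 and len(np.unique(max_r2[~np.isnan(max_r2)])) > 1:
            table = diff.ld_differentiation_table(passing_dels, max_r2, cfg.anchor_r2)
            try:
                chi2, chi2_p = diff.chi2_ld_vs_differentiation(table)
            except ValueError:
                chi2, chi2_p = float("nan"), float("nan")
        else:
            chi2, chi2_p = float("nan"), float("nan")
        in_dc = np.zeros(len(passing_dels), dtype=bool)
        member_ids = {m for c in clusters for m in c.member_deletions}
        for i, sid in enumerate(passing_dels["site_id"]):
            in_dc[i] = sid in member_ids
        summary["differentiation"] = {
            "del_fst_threshold": del_thresh,
            "snp_fst_threshold": snp_thresh,
            "n_passing_deletions": int(len(passing_dels)),
            "n_passing_snps": int(len(passing_snps)),
            "n_anchored_pairs": int(len(anchored)),
            "n_del_dc": len(clusters),
            "del_dc_total_bp": int(sum(c.size for c in clusters)),
            "n_low_ld_deletions": int(len(low_ld)),
            "n_gene_links": int(len(genes)),
            "tss_groups": tss_groups.value_counts().to_dict(),
            "chi2_ld_diff": chi2,
            "chi2_p": chi2_p,
            "implant_recovery": _implant_recovery(truth, passing_dels),
        }
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if out_dir is not None:
        _write_bundle(Path(out_dir), cfg, summary, tables)
    return summary


def _implant_recovery(truth: dict, passing_dels: pd.DataFrame) -> float:
    implanted = set(truth["implanted_deletions"]["site_id"])
    if not implanted:
        return float("nan")
    found = implanted & set(passing_dels["site_id"])
    return len(found) / len(implanted)


def _write_bundle(
    out_dir: Path, cfg: RunConfig, summary: dict, tables: dict[str, pd.DataFrame]
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    for svtype, callers in d["caller"]["eligible"].items():
        d["caller"]["eligible"][svtype] = sorted(callers)
    for caller, prof in d["sim"]["caller_profiles"].items():
        d["sim"]["caller_profiles"][caller] = list(prof)
    return d
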