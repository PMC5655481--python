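"""Readers and writers for the standard formats the pipeline consumes.

VCF handling goes through pysam and supports the symbolic-ALT + INFO/END
dialect emitted by DELLY/Lumpy-style SV callers: SVTYPE and END INFO keys,
optional GT FORMAT.  VCF POS is 1-based; internally everything is 0-based
half-open, so ``start = POS - 1`` and ``end = END``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import (
    SV_TYPES,
    AnnotationSet,
    GenomicInterval,
    GenotypeMatrix,
    PopulationPanel,
    SVCall,
    SVSite,
)

log = logging.getLogger("svpopdiff")


def read_sv_vcf(
    path: str | Path,
    sample: str = "all",
    caller: str | None = None,
):
    """Read an SV VCF into SVSite records (``sample='all'``) or per-sample
    SVCall records (``sample=<id>``).

    Records lacking a parseable SVTYPE in {DEL, INV, DUP} or a usable END are
    skipped and counted; the function returns ``(records, n_skipped)``.
    Unreadable files raise.
    """
    skipped = 0
    records: list = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            svtype = rec.info.get("SVTYPE")
            if svtype is None and rec.alts:
                alt = rec.alts[0]
                if alt.startswith("<") and alt.endswith(">"):
                    svtype = alt.strip("<>").split(":")[0]
            if svtype not in SV_TYPES:
                skipped += 1
                log.debug("skipping record %s:%s with SVTYPE=%r", rec.chrom, rec.pos, svtype)
                continue
            end = rec.stop  # pysam: INFO/END if present, else POS+len(REF)-1
            start = rec.pos - 1
            if end is None or end <= start:
                skipped += 1
                continue
            iv = GenomicInterval(rec.chrom, start, end)
            if sample == "all":
                genotypes = None
                if vcf_samples:
                    genotypes = {}
                    for s in vcf_samples:
                        gt = rec.samples[s].get("GT")
                        if gt is None or any(a is None for a in gt):
                            genotypes[s] = -1
                        else:
                            genotypes[s] = int(sum(1 for a in gt if a and a > 0))
                site_id = rec.id or f"{svtype}_{rec.chrom}_{start}_{i}"
                records.append(SVSite(iv, svtype, site_id, genotypes=genotypes))
            else:
                records.append(
                    SVCall(
                        iv,
                        svtype,
                        caller or "unknown",
                        sample,
                        qual=rec.qual if rec.qual is not None else None,
                    )
                )
    return records, skipped


def write_sv_vcf(
    path: str | Path,
    sites: Sequence[SVSite],
    samples: Sequence[str] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write SVSite records as a symbolic-ALT VCF (uncompressed text).

    When ``samples`` is given, per-sample GT fields are emitted from the
    dosage (0 -> 0/0, 1 -> 0/1, 2 -> 1/1, -1 -> ./.).
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "svpopdiff")
    if chrom_lengths is None:
        chrom_lengths = {}
        for s in sites:
            c = s.interval.chrom
            chrom_lengths[c] = max(chrom_lengths.get(c, 0), s.interval.end + 1)
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=int(length))
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("PRECISE", 0, "Flag", "Breakpoint-resolved site")
    for alt in SV_TYPES:
        header.add_meta(
            "ALT", items=[("ID", alt), ("Description", f"{alt} structural variant")]
        )
    if samples:
        header.formats.add("GT", 1, "String", "Genotype")
        for s in samples:
            header.add_sample(s)
    gt_code = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start)):
            rec = out.new_record(
                contig=site.interval.chrom,
                start=site.interval.start,
                stop=site.interval.end,
                alleles=("N", f"<{site.svtype}>"),
                id=site.site_id,
            )
            rec.info["SVTYPE"] = site.svtype
            if site.precise:
                rec.info["PRECISE"] = True
            if samples:
                gts = site.genotypes or {}
                for s in samples:
                    rec.samples[s]["GT"] = gt_code[int(gts.get(s, -1))]
            out.write(rec)


def read_panel(path: str | Path) -> PopulationPanel:
    """Tab-separated sample/breed/group file, with or without a header line."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = str(first.iloc[0, 0]).lower() == "sample"
    frame = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=None if has_header else ["sample", "breed", "group"],
        dtype=str,
    )
    frame.columns = [c.lower() for c in frame.columns]
    return PopulationPanel(frame)


def write_panel(path: str | Path, panel: PopulationPanel) -> None:
    panel.frame.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ as a chrom/start/end(/name/score/strand) frame, 0-based half-open."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    frame.columns = names[: frame.shape[1]] + list(frame.columns[6:])
    frame["chrom"] = frame["chrom"].astype(str)
    return frame.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


def _gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_transcripts_gff3(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript and intron tracks from a GFF3 gene-model file.

    Returns ``(transcripts, introns)``: transcripts carry chrom/start/end/
    strand/gene_id/transcript_id/tss where tss is the strand-aware
    transcription start coordinate (start for ``+``, end-1 for ``-``);
    introns are the gaps between consecutive exons of each transcript.
    GFF3 is 1-based inclusive and is converted on read.
    """
    cols = [
        "chrom", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    gff = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=cols,
        dtype={"chrom": str},
    )
    gff["start"] = gff["start"].astype(int) - 1  # to 0-based half-open
    gff["end"] = gff["end"].astype(int)

    tx_rows, exon_by_tx = [], {}
    for _, row in gff.iterrows():
        attrs = _gff3_attributes(row["attributes"])
        if row["type"] in ("mRNA", "transcript"):
            tx_id = attrs.get("ID", f"tx_{len(tx_rows)}")
            gene = attrs.get("Parent", attrs.get("gene_id", tx_id))
            tss = row["start"] if row["strand"] == "+" else row["end"] - 1
            tx_rows.append(
                (row["chrom"], row["start"], row["end"], row["strand"],
                 gene, tx_id, tss)
            )
        elif row["type"] == "exon":
            parent = attrs.get("Parent")
            if parent is not None:
                exon_by_tx.setdefault(parent, []).append(
                    (row["chrom"], row["start"], row["end"])
                )
    transcripts = pd.DataFrame(
        tx_rows,
        columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id", "tss"],
    )
    intron_rows = []
    for tx_id, exons in exon_by_tx.items():
        exons.sort(key=lambda e: e[1])
        for (c1, _, e1), (_, s2, _) in zip(exons, exons[1:]):
            if s2 > e1:
                intron_rows.append((c1, e1, s2, tx_id))
    introns = pd.DataFrame(
        intron_rows, columns=["chrom", "start", "end", "transcript_id"]
    )
    return (
        transcripts.sort_values(["chrom", "start"]).reset_index(drop=True),
        introns.sort_values(["chrom", "start"]).reset_index(drop=True),
    )


def read_annotations(
    te: str | Path | None = None,
    vntr: str | Path | None = None,
    lqlc: str | Path | None = None,
    gff3: str | Path | None = None,
) -> AnnotationSet:
    """Assemble an AnnotationSet from BED tracks and an optional GFF3."""
    ann = AnnotationSet()
    for name, p in (("te", te), ("vntr", vntr), ("lqlc", lqlc)):
        if p is not None:
            ann.add(name, read_bed(p))
    if gff3 is not None:
        transcripts, introns = read_transcripts_gff3(gff3)
        ann.add("transcripts", transcripts)
        if len(introns):
            ann.add("introns", introns)
    return ann


def read_snp_matrix(path: str | Path) -> GenotypeMatrix:
    """Load a biallelic SNP VCF with GT fields as a GenotypeMatrix.

    Sites get svtype ``SNP`` and a 1 bp interval at POS; multi-allelic
    records are skipped.
    """
    rows, dosages = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: SNP VCF carries no samples")
        for i, rec in enumerate(vcf):
            if rec.alts is None or len(rec.alts) != 1:
                continue
            start = rec.pos - 1
            rows.append(
                (rec.chrom, start, start + 1, "SNP", rec.id or f"snp_{rec.chrom}_{start}")
            )
            ds = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    ds.append(-1)
                else:
                    ds.append(sum(1 for a in gt if a and a > 0))
            dosages.append(ds)
    sites = pd.DataFrame(rows, columns=list(GenotypeMatrix.SITE_COLUMNS))
    dosage = (
        np.array(dosages, dtype=np.int16).T
        if dosages
        else np.zeros((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(sites, samples, dosage)


def write_snp_matrix(
    path: str | Path,
    matrix: GenotypeMatrix,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write a SNP GenotypeMatrix as a minimal biallelic A/C VCF."""
    header = pysam.VariantHeader()
    header.add_meta("source", "svpopdiff")
    if chrom_lengths is None:
        chrom_lengths = (
            matrix.sites.groupby("chrom")["end"].max() + 1
        ).to_dict()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(str(chrom), length=int(length))
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    gt_code = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(matrix.n_sites):
            row = matrix.sites.iloc[j]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["start"]),
                stop=int(row["start"]) + 1,
                alleles=("A", "C"),
                id=str(row["site_id"]),
            )
            for i, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_code[int(matrix.dosage[i, j])]
            out.write(rec)


def matrix_from_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Load a genotyped (SV or SNP) VCF as a GenotypeMatrix."""
    sites, skipped = read_sv_vcf(path, sample="all")
    genotyped = [s for s in sites if s.genotypes is not None]
    if not genotyped:
        raise ValueError(f"{path}: no genotyped records")
    samples = sorted(genotyped[0].genotypes)
    return GenotypeMatrix.from_sv_sites(genotyped, samples), skipped


def matrix_to_vcf(
    path: str | Path,
    matrix: GenotypeMatrix,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    write_sv_vcf(path, matrix.to_sv_sites(), matrix.samples, chrom_lengths)
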