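"""Readers and writers for the formats the pipeline exchanges.

VCF v4.2 (FORMAT ``GT:GQ:GC``), FASTA (60-column wrap), BED (0-based
half-open), calls/metadata CSV and plain-text contig lists.  All writers
are deterministic so that fixed-seed runs produce byte-identical files.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .ascertainment import HET, HOM_ALT, HOM_REF, NULL, FilterLedger, VariantRecord
from .matrix import GenotypeMatrix, SAMPLE_META_COLUMNS

logger = logging.getLogger(__name__)

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", NULL: "./."}

_INFO_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(reference: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in sorted(reference):
            fh.write(f">{contig}\n")
            seq = reference[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    records: Sequence[dict],
    contig_lengths: dict[str, int],
    path,
    samples: Sequence[str] = ("single_haploid", "pool_diploid"),
    source: str = "rad",
) -> None:
    """Write simulator records as a VCF v4.2 with FORMAT ``GT:GQ:GC``.

    RAD confidences go into the GC (genotype confidence) field, RNA
    confidences into GQ.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=snpforge-simulator",
    ]
    for contig in sorted(contig_lengths):
        lines.append(f"##contig=<ID={contig},length={contig_lengths[contig]}>")
    for name in _INFO_FIELDS:
        lines.append(f'##INFO=<ID={name},Number=1,Type=Float,Description="{name}">')
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=GC,Number=1,Type=Float,Description="Genotype confidence">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    ordered = sorted(records, key=lambda r: (r["contig"], r["pos"]))
    for rec in ordered:
        annotations = rec.get("annotations") or {}
        info = (
            ";".join(f"{k}={annotations[k]:g}" for k in _INFO_FIELDS if k in annotations)
            or "."
        )
        fields = []
        for sample in samples:
            gt = _GT_STRING[rec["genotypes"].get(sample, NULL)]
            conf = rec.get("confidences", {}).get(sample)
            if conf is None:
                gq = gc = "."
            elif source == "rad":
                gq, gc = ".", f"{float(conf):.2f}"
            else:
                gq, gc = str(int(conf)), "."
            fields.append(f"{gt}:{gq}:{gc}")
        lines.append(
            "\t".join(
                [
                    rec["contig"],
                    str(rec["pos"]),
                    ".",
                    rec["ref"],
                    rec["alt"],
                    ".",
                    ".",
                    info,
                    "GT:GQ:GC",
                ]
                + fields
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path, source: str = "rad") -> list[VariantRecord]:
    """Parse a VCF into variant records; multiallelic sites are split.

    The per-sample confidence is taken from the GC FORMAT field for RAD
    input and from GQ for RNA input.  Genotypes involving another ALT
    allele of a split multiallelic site become NULL in each sub-record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    records: list[VariantRecord] = []
    for row_num, v in enumerate(vcf, start=1):
        if len(v.ALT) > 1:
            logger.warning(
                "multiallelic site %s:%s split into %d records", v.CHROM, v.POS, len(v.ALT)
            )
        def _fmt(field):
            try:
                return v.format(field)
            except KeyError:
                return None

        gq = _fmt("GQ")
        gc = _fmt("GC")
        annotations = {}
        for name in _INFO_FIELDS:
            value = v.INFO.get(name)
            if value is not None:
                annotations[name] = float(value)
        for alt_idx, alt in enumerate(v.ALT, start=1):
            calls, confidences = {}, {}
            for si, sample in enumerate(sample_names):
                alleles = [a for a in v.genotypes[si][:-1]]
                if any(a < 0 for a in alleles):
                    calls[sample] = NULL
                elif all(a == alt_idx for a in alleles):
                    calls[sample] = HOM_ALT
                elif all(a == 0 for a in alleles):
                    calls[sample] = HOM_REF
                elif sorted(set(alleles)) == [0, alt_idx]:
                    calls[sample] = HET
                else:  # involves a different ALT allele
                    calls[sample] = NULL
                conf = None
                raw = gc if source == "rad" else gq
                if raw is not None:
                    value = float(np.asarray(raw[si]).ravel()[0])
                    if np.isfinite(value) and value > -(2**30):
                        conf = value
                confidences[sample] = conf
            try:
                records.append(
                    VariantRecord(
                        contig=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        source=source,
                        calls=calls,
                        confidences=confidences,
                        annotations=dict(annotations),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"malformed VCF record at data line {row_num}: {exc}") from exc
    return records


def write_tagged_vcf(
    variants: Sequence[VariantRecord],
    ledger: FilterLedger,
    contig_lengths: dict[str, int],
    path,
) -> None:
    """Write variants with their filter tags in the FILTER column."""
    records = []
    for v in variants:
        records.append(v)
    lines = ["##fileformat=VCFv4.2"]
    for contig in sorted(contig_lengths):
        lines.append(f"##contig=<ID={contig},length={contig_lengths[contig]}>")
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    tags = sorted({t for v in variants for t in ledger.tags_of(v.key)})
    for tag in tags:
        lines.append(f'##FILTER=<ID={tag},Description="{tag}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(records, key=lambda x: (x.contig, x.pos)):
        tag_set = ledger.tags_of(v.key)
        filt = ";".join(sorted(tag_set)) if tag_set else "PASS"
        lines.append(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t.")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED and contig lists
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write ``(contig, start, end[, name])`` rows, 0-based half-open."""
    with open(path, "w") as fh:
        for row in intervals:
            name = row[3] if len(row) > 3 else "region"
            fh.write(f"{row[0]}\t{row[1]}\t{row[2]}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "region"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def read_contig_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# call matrices
# ---------------------------------------------------------------------------


def write_calls(matrix: GenotypeMatrix, calls_path, samples_path=None) -> None:
    matrix.to_letters().rename_axis("sample_id").to_csv(calls_path)
    if samples_path is not None:
        meta = matrix.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(samples_path)


def read_calls(calls_path, samples_path) -> GenotypeMatrix:
    """Load a calls table plus sample metadata into a genotype matrix.

    Letter (AA/AB/BB/NoCall) and numeric (0/1/2/-1) encodings are both
    accepted.  Samples present in the calls but absent from the metadata
    are an error.
    """
    raw = pd.read_csv(calls_path, index_col=0, dtype=str)
    try:
        calls = GenotypeMatrix.letters_to_codes(raw)
    except ValueError as exc:
        # locate the offending cell for a useful message
        for sample in raw.index:
            for snp in raw.columns:
                token = raw.loc[sample, snp]
                try:
                    GenotypeMatrix.letters_to_codes(pd.DataFrame({"x": [token]}))
                except ValueError:
                    raise ValueError(
                        f"unknown genotype token {token!r} at sample {sample!r}, SNP {snp!r}"
                    ) from exc
        raise
    meta = pd.read_csv(samples_path, index_col=0)
    missing = set(calls.index) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    meta = meta.loc[calls.index]
    for col in SAMPLE_META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    snps = pd.DataFrame(index=calls.columns)
    snps["source"] = "rna"
    return GenotypeMatrix(calls, meta, snps)


def read_structure_likelihoods(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "K" not in df.columns:
        raise ValueError("likelihood table needs a 'K' column")
    return df
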