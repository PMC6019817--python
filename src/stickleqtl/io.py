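"""Readers and writers for the interchange formats.

TSV dialect: tab-separated, UTF-8, mandatory header row, "NA" for missing
scalars. All genomic coordinates are 1-based inclusive (VCF convention)
except BED output, which is converted to 0-based half-open at write time
only.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SchemaError
from .screen import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Call,
    ClusterReport,
    ConcordanceRecord,
    SamplePanel,
    VariantRecord,
)

log = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["fish_id", "family", "sex", "std_length_mm", "tooth_total"]
_GT_TO_VCF = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: phenotype TSV missing column(s) {missing}")
    if (df["std_length_mm"] <= 0).any():
        bad = df.index[df["std_length_mm"] <= 0][0] + 2  # 1-based incl. header
        raise SchemaError(f"{path}: line {bad}: std_length_mm must be > 0")
    if (df["tooth_total"] < 0).any():
        bad = df.index[df["tooth_total"] < 0][0] + 2
        raise SchemaError(f"{path}: line {bad}: tooth_total must be >= 0")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic records as VCFv4.2 with QUAL, GT and GQ."""
    lines = ["##fileformat=VCFv4.2"]
    contigs = contig_lengths or {}
    seen = {v.chrom for v in variants}
    for chrom in sorted(seen):
        if chrom in contigs:
            lines.append(f"##contig=<ID={chrom},length={contigs[chrom]}>")
        else:
            lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for v in sorted(variants, key=lambda r: (r.chrom, r.pos)):
        fields = [
            v.chrom,
            str(v.pos),
            ".",
            v.ref,
            v.alt,
            f"{v.site_quality:.2f}",
            ".",
            ".",
            "GT:GQ",
        ]
        for s in samples:
            c = v.calls.get(s, Call(MISSING, None))
            gq = "." if c.gq is None or c.genotype == MISSING else str(int(round(c.gq)))
            fields.append(f"{_GT_TO_VCF[c.genotype]}:{gq}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, splitting multiallelic sites.

    When a site is split, sample alleles equal to another alt are treated as
    missing for the split record. Symbolic alleles are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    for rec in vcf:
        alts = rec.ALT
        if not alts:
            continue
        gq_arr = None
        try:
            gq_arr = rec.format("GQ")
        except KeyError:
            pass
        genos = rec.genotypes  # [allele1, allele2, phased]
        for alt_i, alt in enumerate(alts, start=1):
            if alt.startswith("<") or "*" in alt:
                raise SchemaError(f"{path}: {rec.CHROM}:{rec.POS}: symbolic allele {alt!r}")
            calls: dict[str, Call] = {}
            for si, s in enumerate(samples):
                a, b = genos[si][0], genos[si][1]
                gq = None
                if gq_arr is not None:
                    raw = int(gq_arr[si][0])
                    gq = None if raw < 0 else float(raw)
                if a < 0 or b < 0:
                    calls[s] = Call(MISSING, None)
                    continue
                pair = {a, b}
                other_alts = pair - {0, alt_i}
                if other_alts:
                    calls[s] = Call(MISSING, None)  # carries a different alt
                    continue
                n_alt = (a == alt_i) + (b == alt_i)
                calls[s] = Call([HOM_REF, HET, HOM_ALT][n_alt], gq)
            out.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    site_quality=float(rec.QUAL) if rec.QUAL is not None else float("nan"),
                    calls=calls,
                )
            )
    return out


# ---------------------------------------------------------------------------
# sample manifest
# ---------------------------------------------------------------------------

def read_sample_panel(path: str | Path) -> SamplePanel:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "qtl_status", "coverage"):
        if col not in df.columns:
            raise SchemaError(f"{path}: sample manifest missing column {col!r}")
    try:
        return SamplePanel(
            status=dict(zip(df["sample_id"], df["qtl_status"])),
            coverage=dict(zip(df["sample_id"], df["coverage"])),
        )
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def write_sample_panel(panel: SamplePanel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": panel.samples,
            "qtl_status": [panel.status[s] for s in panel.samples],
            "coverage": [panel.coverage[s] for s in panel.samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# expression matrices, groups, GMT
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate gene id {dup!r}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"{path}: groups TSV missing column {col!r}")
    return dict(zip(df["sample_id"], df["group"]))


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: set name, description, then member gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_concordance(records: Sequence[ConcordanceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "class": r.variant_class,
                "score": r.score,
                "p_pos": r.p_pos,
                "p_neg": r.p_neg,
                "n_called_pos": r.n_called_pos,
                "n_called_neg": r.n_called_neg,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_cluster_bed(report: ClusterReport, chrom: str, path: str | Path,
                      name: str = "perfect_cluster") -> None:
    """BED (0-based half-open) of the perfect-variant span; empty if no span."""
    with open(path, "w", encoding="utf-8") as fh:
        if report.min_pos is not None and report.max_pos is not None:
            fh.write(f"{chrom}\t{report.min_pos - 1}\t{report.max_pos}\t{name}\n")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_config(path: str | Path) -> dict:
    """Plain-text key-value (YAML) run configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a key-value mapping")
    return cfg
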