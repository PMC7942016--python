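"""Readers and writers for the package's plain-text formats.

Genotypes travel as VCF 4.2 (GT field only, read back through cyvcf2),
counts and expression as TSV with a header row, site and 3'-UTR
annotations as BED6 (0-based half-open; internal coordinates are 1-based
inclusive), UTR sequences as FASTA, and miRNA definitions as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .mirna import MirnaRecord
from .qtl import GenotypeTable
from .quant import SiteCounts


# --- VCF -----------------------------------------------------------------

def write_vcf(gt: GenotypeTable, path) -> None:
    """Write a GT-only VCF; phased genotypes when haplotypes are present."""
    path = Path(path)
    order = np.argsort(gt.pos, kind="stable")
    contigs = list(dict.fromkeys(gt.chrom[order].tolist()))
    sep = "|" if gt.haplotypes is not None else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.samples)
            + "\n"
        )
        for j in order:
            calls = []
            for i in range(gt.n_samples):
                d = gt.dosage[j, i]
                if np.isnan(d):
                    calls.append(f".{sep}.")
                elif gt.haplotypes is not None:
                    h0 = int(gt.haplotypes[0, j, i])
                    h1 = int(gt.haplotypes[1, j, i])
                    calls.append(f"{h0}{sep}{h1}")
                else:
                    d = int(d)
                    calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(
                f"{gt.chrom[j]}\t{gt.pos[j]}\t{gt.snp_ids[j]}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path) -> GenotypeTable:
    """Load genotypes (GT field) into a GenotypeTable via cyvcf2."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, pos, dosage_rows, hap_rows = [], [], [], [], []
    phased_all = True
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        dos, h0s, h1s = [], [], []
        for g in var.genotypes:
            a0, a1, phased = g[0], g[1], g[2]
            if a0 < 0 or a1 < 0:
                dos.append(np.nan)
                h0s.append(np.nan)
                h1s.append(np.nan)
            else:
                dos.append(float(a0 + a1))
                h0s.append(float(a0))
                h1s.append(float(a1))
                phased_all = phased_all and bool(phased)
        dosage_rows.append(dos)
        hap_rows.append((h0s, h1s))
    haplotypes = None
    if phased_all and dosage_rows:
        haplotypes = np.array(
            [[r[0] for r in hap_rows], [r[1] for r in hap_rows]], dtype=float
        )
    return GenotypeTable(
        samples=samples,
        snp_ids=np.array(snp_ids),
        chrom=np.array(chroms),
        pos=np.array(pos, dtype=np.int64),
        dosage=np.array(dosage_rows, dtype=float),
        haplotypes=haplotypes,
    )


# --- counts and expression TSV ------------------------------------------

def write_counts_tsv(counts: SiteCounts, path) -> None:
    """Two columns per sample (<sample>.A, <sample>.G) plus site metadata."""
    blocks = [counts.sites]
    for s in counts.samples:
        blocks.append(counts.a[s].rename(f"{s}.A"))
        blocks.append(counts.g[s].rename(f"{s}.G"))
    pd.concat(blocks, axis=1).to_csv(path, sep="\t", index_label="site")


def read_counts_tsv(path, allelic_path=None) -> SiteCounts:
    df = pd.read_csv(path, sep="\t", index_col="site")
    meta_cols = ["chrom", "pos", "strand", "gene"]
    sites = df[meta_cols]
    samples = sorted({c[:-2] for c in df.columns if c.endswith(".A")})
    a = df[[f"{s}.A" for s in samples]].copy()
    a.columns = samples
    g = df[[f"{s}.G" for s in samples]].copy()
    g.columns = samples
    allelic = None
    if allelic_path is not None and Path(allelic_path).exists():
        allelic = pd.read_csv(allelic_path, sep="\t")
    return SiteCounts(sites=sites, a=a.astype(int), g=g.astype(int), allelic=allelic)


def write_allelic_tsv(allelic: pd.DataFrame, path) -> None:
    allelic.to_csv(path, sep="\t", index=False)


def read_allelic_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene", float_precision="round_trip")


# --- BED -----------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def sites_to_bed(sites: pd.DataFrame) -> pd.DataFrame:
    """1-based site positions to BED6 intervals (p-1, p)."""
    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"].astype(int) - 1,
            "end": sites["pos"].astype(int),
            "name": sites.index,
            "score": 0,
            "strand": sites["strand"],
        }
    ).reset_index(drop=True)


def write_bed(bed: pd.DataFrame, path) -> None:
    bed[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)


# --- FASTA ---------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# --- miRNA table ----------------------------------------------------------

def write_mirna_tsv(mirnas, path) -> None:
    rows = []
    tissues = sorted({t for m in mirnas for t in m.proxy})
    for m in mirnas:
        row = {
            "name": m.name,
            "seq": m.seq,
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
        }
        for t in tissues:
            row[f"proxy.{t}"] = m.proxy.get(t, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_mirna_tsv(path) -> list[MirnaRecord]:
    df = pd.read_csv(path, sep="\t")
    proxy_cols = [c for c in df.columns if c.startswith("proxy.")]
    out = []
    for _, row in df.iterrows():
        proxy = {c[len("proxy."):]: float(row[c]) for c in proxy_cols}
        out.append(
            MirnaRecord(
                name=row["name"],
                seq=row["seq"],
                chrom=row.get("chrom", ""),
                start=int(row.get("start", 0)),
                end=int(row.get("end", 0)),
                strand=row.get("strand", "+"),
                proxy=proxy,
            )
        )
    return out


# --- summary statistics ---------------------------------------------------

def read_summary_stats(path) -> pd.DataFrame:
    """TSV with columns snp, beta, se (optionally p, n, maf, sign)."""
    df = pd.read_csv(path, sep="\t")
    if "snp" not in df.columns:
        raise ValueError("summary statistics need a 'snp' column")
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- config ----------------------------------------------------------------

def write_config_json(obj: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
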