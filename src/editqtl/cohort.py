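"""Cohort bundles: simulate a full multi-tissue study and round-trip it to disk.

A cohort ties together genotypes, ground truth, per-tissue read counts and
expression, miRNA definitions with per-tissue proxy levels, and 3'-UTR
annotation with sequences — everything the downstream edQTL, ASED,
colocalization and discovery stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .mirna import MirnaRecord
from .qtl import GenotypeTable
from .quant import SiteCounts
from .synthetic import (
    CohortConfig,
    MirnaCoupling,
    SimTruth,
    SiteTruth,
    plant_utr,
    simulate_editing_counts,
    simulate_expression,
    simulate_genotypes,
    simulate_truth,
)

_UTR_LEN = 120
_UTR_EDIT_OFFSET = 60  # 1-based position of the site inside a default UTR


@dataclass
class Cohort:
    cfg: CohortConfig
    gt: GenotypeTable
    truth: SimTruth
    counts: dict[str, SiteCounts]
    expression: dict[str, pd.DataFrame]
    mirnas: list[MirnaRecord] = field(default_factory=list)
    utr_bed: pd.DataFrame | None = None
    utr_seqs: dict[str, str] = field(default_factory=dict)

    @property
    def sites(self) -> pd.DataFrame:
        return self.truth.site_table()

    def mirna_levels(self) -> dict[str, dict[str, float]]:
        return {m.name: dict(m.proxy) for m in self.mirnas}


def _random_utr(rng: np.random.Generator, length: int, edit_offset: int) -> str:
    bases = rng.choice(list("ACGU"), size=length)
    seq = "".join(bases)
    return seq[: edit_offset - 1] + "A" + seq[edit_offset:]


def simulate_cohort(
    cfg: CohortConfig,
    n_sites: int = 20,
    n_snps: int | None = None,
    baseline_range: tuple[float, float] = (0.2, 0.5),
    slope_range: tuple[float, float] = (0.6, 1.2),
    frac_null: float = 0.0,
    couplings: Mapping[int, MirnaCoupling] | None = None,
    mirnas: Sequence[MirnaRecord] = (),
    baseline_expr: float = 100.0,
    expr_noise_sd: float = 0.1,
) -> Cohort:
    """Simulate genotypes, truth, counts, expression and annotation.

    ``couplings`` maps site indices (0-based, in truth order) to miRNA
    degradation couplings; the named miRNAs must appear in ``mirnas`` with
    per-tissue proxy levels, which scale the effective degradation rate in
    each tissue.  Coupled sites get a 3'-UTR sequence with a planted
    editing-specific seed site; every other site gets a random UTR with an
    A at the editing position.
    """
    if n_snps is None:
        n_snps = max(3 * n_sites, 30)
    gt = simulate_genotypes(cfg.n_individuals, n_snps, cfg.maf_range, seed=cfg.seed)
    truth = simulate_truth(
        gt,
        n_sites,
        seed=cfg.seed + 1,
        baseline_range=baseline_range,
        slope_range=slope_range,
        frac_null=frac_null,
        couplings=couplings,
    )
    levels = {m.name: dict(m.proxy) for m in mirnas}
    counts, expression = {}, {}
    for tissue in cfg.tissues:
        counts[tissue] = simulate_editing_counts(gt, truth, cfg, tissue, levels)
        expression[tissue] = simulate_expression(
            gt, truth, cfg, tissue, levels,
            baseline_expr=baseline_expr, noise_sd=expr_noise_sd,
        )
    mirna_by_name = {m.name: m for m in mirnas}
    rng = np.random.default_rng(cfg.seed + 2)
    utr_rows, utr_seqs = [], {}
    for st in truth:
        if st.mirna is not None and st.mirna.name in mirna_by_name:
            seq, edit_pos = plant_utr(
                mirna_by_name[st.mirna.name],
                st.mirna.target_version,
                seed=cfg.seed + 3,
                length=_UTR_LEN,
            )
        else:
            seq, edit_pos = _random_utr(rng, _UTR_LEN, _UTR_EDIT_OFFSET), _UTR_EDIT_OFFSET
        # interval placed so the 1-based site position maps to edit_pos
        start = st.pos - edit_pos  # 0-based half-open
        utr_rows.append((st.chrom, start, start + len(seq), st.gene, 0, st.strand))
        utr_seqs[st.gene] = seq
    utr_bed = pd.DataFrame(utr_rows, columns=eio.BED_COLUMNS)
    return Cohort(
        cfg=cfg,
        gt=gt,
        truth=truth,
        counts=counts,
        expression=expression,
        mirnas=list(mirnas),
        utr_bed=utr_bed,
        utr_seqs=utr_seqs,
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Emit the cohort as VCF + TSV + BED + FASTA files under outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_vcf(cohort.gt, out / "genotypes.vcf")
    for tissue in cohort.cfg.tissues:
        sc = cohort.counts[tissue]
        eio.write_counts_tsv(sc, out / f"counts.{tissue}.tsv")
        if sc.allelic is not None and len(sc.allelic):
            eio.write_allelic_tsv(sc.allelic, out / f"allelic.{tissue}.tsv")
        eio.write_expression_tsv(
            cohort.expression[tissue], out / f"expression.{tissue}.tsv"
        )
    eio.write_bed(eio.sites_to_bed(cohort.sites), out / "sites.bed")
    if cohort.utr_bed is not None:
        eio.write_bed(cohort.utr_bed, out / "utr3.bed")
    if cohort.utr_seqs:
        eio.write_fasta(cohort.utr_seqs, out / "utr3.fasta")
    if cohort.mirnas:
        eio.write_mirna_tsv(cohort.mirnas, out / "mirna.tsv")
    cohort.truth.to_frame().to_csv(
        out / "truth.tsv", sep="\t", index=False, float_format="%.17g"
    )
    cfg = cohort.cfg
    eio.write_config_json(
        {
            "n_individuals": cfg.n_individuals,
            "tissues": list(cfg.tissues),
            "enzyme_scalar": dict(cfg.enzyme_scalar),
            "maf_range": list(cfg.maf_range),
            "coverage_mean": cfg.coverage_mean,
            "dispersion": cfg.dispersion,
            "seed": cfg.seed,
        },
        out / "config.json",
    )


def read_cohort(outdir) -> Cohort:
    """Load a cohort written by :func:`write_cohort`."""
    out = Path(outdir)
    raw = eio.read_config_json(out / "config.json")
    cfg = CohortConfig(
        n_individuals=raw["n_individuals"],
        tissues=tuple(raw["tissues"]),
        enzyme_scalar=raw["enzyme_scalar"],
        maf_range=tuple(raw["maf_range"]),
        coverage_mean=raw["coverage_mean"],
        dispersion=raw["dispersion"],
        seed=raw["seed"],
    )
    gt = eio.read_vcf(out / "genotypes.vcf")
    tf = pd.read_csv(out / "truth.tsv", sep="\t", float_precision="round_trip")
    sites = []
    for _, r in tf.iterrows():
        coupling = None
        if isinstance(r["mirna"], str) and r["mirna"]:
            coupling = MirnaCoupling(r["mirna"], r["target_version"], float(r["d"]))
        sites.append(
            SiteTruth(
                site=r["site"], chrom=r["chrom"], pos=int(r["pos"]),
                strand=r["strand"], gene=r["gene"], snp=r["snp"],
                baseline_phi=float(r["baseline_phi"]),
                true_slope=float(r["true_slope"]), mirna=coupling,
            )
        )
    truth = SimTruth(sites)
    counts, expression = {}, {}
    for tissue in cfg.tissues:
        counts[tissue] = eio.read_counts_tsv(
            out / f"counts.{tissue}.tsv", out / f"allelic.{tissue}.tsv"
        )
        expression[tissue] = eio.read_expression_tsv(out / f"expression.{tissue}.tsv")
    mirna_path = out / "mirna.tsv"
    mirnas = eio.read_mirna_tsv(mirna_path) if mirna_path.exists() else []
    utr_path = out / "utr3.bed"
    utr_bed = eio.read_bed(utr_path) if utr_path.exists() else None
    fasta_path = out / "utr3.fasta"
    utr_seqs = eio.read_fasta(fasta_path) if fasta_path.exists() else {}
    return Cohort(
        cfg=cfg, gt=gt, truth=truth, counts=counts, expression=expression,
        mirnas=mirnas, utr_bed=utr_bed, utr_seqs=utr_seqs,
    )
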