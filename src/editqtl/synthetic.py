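"""Synthetic cohorts with the statistical structure the analysis assumes.

Genotypes are drawn under Hardy-Weinberg equilibrium; a causal SNP shifts
the latent editing level of its site additively on the logit scale, scaled
by a per-tissue enzyme multiplier emulating ADAR/ADARB1 abundance; read
counts are Poisson totals with beta-binomial edited reads; heterozygotes
carry explicit haplotypes so allele-resolved counts are available; and an
optional miRNA coupling degrades the edited or unedited transcript pool,
distorting both observed editing and steady-state expression exactly as
the forward degradation model prescribes.

Every draw is driven by a single integer seed: fixing the seed fixes every
emitted byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .mirna import MirnaRecord, degradation_model, normalize_rna, revcomp_rna, seed_match, editing_specific_target
from .qtl import GenotypeTable
from .quant import SiteCounts


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    enzyme_scalar multiplies the genotype effect on the logit of the
    editing level per tissue (a low-ADAR tissue such as skeletal muscle
    gets a value well below 1).  dispersion is the beta-binomial
    overdispersion of edited read counts; 0 recovers the binomial.
    """

    n_individuals: int = 200
    tissues: Sequence[str] = ("tissue_a",)
    enzyme_scalar: Mapping[str, float] = field(default_factory=dict)
    maf_range: tuple[float, float] = (0.1, 0.5)
    coverage_mean: float = 50.0
    dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 3:
            raise ValueError("need at least 3 individuals")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0 <= self.dispersion < 1:
            raise ValueError("dispersion must lie in [0, 1)")
        self.enzyme_scalar = {t: float(self.enzyme_scalar.get(t, 1.0)) for t in self.tissues}
        for t, v in self.enzyme_scalar.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"enzyme_scalar[{t}] must lie in [0, 1]")

    def tissue_rng(self, tissue: str, stream: int = 0) -> np.random.Generator:
        idx = list(self.tissues).index(tissue)
        return np.random.default_rng([self.seed, stream, idx])


@dataclass
class MirnaCoupling:
    """Editing-specific miRNA degradation acting on one site's gene."""

    name: str
    target_version: Literal["unedited", "edited"]
    d: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("degradation rate d must lie in [0, 1]")


@dataclass
class SiteTruth:
    """Ground truth for one simulated editing site."""

    site: str
    chrom: str
    pos: int  # 1-based
    strand: str
    gene: str
    snp: str  # causal SNP id
    baseline_phi: float
    true_slope: float  # per-alt-allele shift of logit(Phi)
    mirna: MirnaCoupling | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_phi < 1.0:
            raise ValueError("baseline_phi must lie in (0, 1)")


@dataclass
class SimTruth:
    sites: list[SiteTruth]

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "strand": [s.strand for s in self.sites],
                "gene": [s.gene for s in self.sites],
            },
            index=pd.Index([s.site for s in self.sites], name="site"),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "site": s.site,
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "strand": s.strand,
                    "gene": s.gene,
                    "snp": s.snp,
                    "baseline_phi": s.baseline_phi,
                    "true_slope": s.true_slope,
                    "mirna": s.mirna.name if s.mirna else "",
                    "target_version": s.mirna.target_version if s.mirna else "",
                    "d": s.mirna.d if s.mirna else 0.0,
                }
            )
        return pd.DataFrame(rows)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    chrom: str = "chr1",
    start: int = 100_000,
    mean_spacing: int = 2_000,
) -> GenotypeTable:
    """Hardy-Weinberg genotypes for n individuals at m cis SNPs.

    Each SNP's alternate-allele frequency is drawn uniformly from
    maf_range (the alternate allele is the minor one), haplotypes are
    independent Bernoulli draws, and dosage is their sum (0/1/2 coding
    Ref:Ref, Ref:Alt, Alt:Alt).  Positions are strictly increasing along
    one chromosome with roughly mean_spacing bp between SNPs.
    """
    if n < 3 or m < 1:
        raise ValueError("need n >= 3 individuals and m >= 1 SNPs")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=m)
    haps = (rng.random((2, m, n)) < freqs[None, :, None]).astype(float)
    gaps = rng.integers(max(2, mean_spacing // 2), mean_spacing * 2, size=m)
    pos = start + np.cumsum(gaps)
    samples = [f"ind{i+1:04d}" for i in range(n)]
    snp_ids = np.array([f"rs{i+1:05d}" for i in range(m)])
    return GenotypeTable(
        samples=samples,
        snp_ids=snp_ids,
        chrom=np.array([chrom] * m),
        pos=pos,
        dosage=haps.sum(axis=0),
        haplotypes=haps,
    )


def simulate_truth(
    gt: GenotypeTable,
    n_sites: int,
    seed: int = 0,
    baseline_range: tuple[float, float] = (0.2, 0.5),
    slope_range: tuple[float, float] = (0.6, 1.2),
    frac_null: float = 0.0,
    couplings: Mapping[int, MirnaCoupling] | None = None,
    site_offset: int = 17,
) -> SimTruth:
    """Assign causal SNPs, baselines and logit-scale slopes to n_sites sites.

    Sites are placed ``site_offset`` bp downstream of their causal SNP (a
    position never occupied by a SNP).  A fraction ``frac_null`` of sites
    gets slope 0; ``couplings`` maps site indices to miRNA degradation
    couplings.
    """
    rng = np.random.default_rng(seed)
    if n_sites > gt.n_snps:
        raise ValueError("more sites than available causal SNPs")
    causal = rng.choice(gt.n_snps, size=n_sites, replace=False)
    causal.sort()
    sites = []
    for k, j in enumerate(causal):
        slope = float(rng.uniform(*slope_range)) * (1 if rng.random() < 0.5 else -1)
        if rng.random() < frac_null:
            slope = 0.0
        coupling = couplings.get(k) if couplings else None
        sites.append(
            SiteTruth(
                site=f"site{k+1:04d}",
                chrom=str(gt.chrom[j]),
                pos=int(gt.pos[j]) + site_offset,
                strand="+",
                gene=f"gene{k+1:04d}",
                snp=str(gt.snp_ids[j]),
                baseline_phi=float(rng.uniform(*baseline_range)),
                true_slope=slope,
                mirna=coupling,
            )
        )
    return SimTruth(sites)


def _effective_d(st: SiteTruth, tissue: str, mirna_levels) -> float:
    if st.mirna is None:
        return 0.0
    level = 1.0
    if mirna_levels is not None:
        level = float(mirna_levels.get(st.mirna.name, {}).get(tissue, 0.0))
    return st.mirna.d * level


def _haplotype_phi(st: SiteTruth, enzyme: float, hap_alt: np.ndarray) -> np.ndarray:
    return expit(logit(st.baseline_phi) + enzyme * st.true_slope * hap_alt)


def latent_phi_and_expression(
    st: SiteTruth,
    gt: GenotypeTable,
    enzyme: float,
    d_eff: float,
):
    """Per-sample latent (Phi', E) and per-haplotype values for hets.

    Every genotype follows the sample-level dosage formula
    Phi = expit(logit(baseline) + enzyme*slope*dosage).  Heterozygotes are
    a mixture of two haplotype transcript pools whose logits sit
    symmetrically around the heterozygote logit, the alt-carrying
    haplotype higher by exactly enzyme*slope — the per-allele cis effect —
    so the pooled mean tracks the dosage formula while allele-resolved
    counts carry the full allelic contrast.  Degradation then reshapes
    each transcript pool.
    Returns (phi_sample, e_sample, hap_detail) where hap_detail maps
    sample index -> (phi_ref', phi_alt', e_ref, e_alt) for heterozygotes.
    """
    j = gt.snp_index(st.snp)
    dos = gt.dosage[j]
    target = st.mirna.target_version if st.mirna else "unedited"
    phi_lat = expit(logit(st.baseline_phi) + enzyme * st.true_slope * dos)
    phi_prime, e_samp = degradation_model(phi_lat, d_eff, target)
    phi_prime = np.array(phi_prime, dtype=float)
    e_samp = np.array(e_samp, dtype=float)
    hap_detail: dict[int, tuple[float, float, float, float]] = {}
    het_idx = np.flatnonzero(dos == 1)
    if het_idx.size and gt.haplotypes is not None:
        eta_het = logit(st.baseline_phi) + enzyme * st.true_slope
        es = enzyme * st.true_slope
        phi_ref = float(expit(eta_het - es / 2.0))
        phi_alt = float(expit(eta_het + es / 2.0))
        ppr, er = degradation_model(phi_ref, d_eff, target)
        ppa, ea = degradation_model(phi_alt, d_eff, target)
        ppr, er, ppa, ea = float(ppr), float(er), float(ppa), float(ea)
        for i in het_idx:
            hap_detail[int(i)] = (ppr, ppa, er, ea)
            e_mix = (er + ea) / 2.0
            phi_mix = (ppr * er + ppa * ea) / (er + ea)
            phi_prime[i] = phi_mix
            e_samp[i] = e_mix
    return phi_prime, e_samp, hap_detail


def _betabin_draw(rng: np.random.Generator, n, phi, dispersion: float):
    n = np.asarray(n)
    phi = np.asarray(phi, dtype=float)
    if dispersion < 1e-12:
        return rng.binomial(n, phi)
    a = phi * (1 - dispersion) / dispersion
    b = (1 - phi) * (1 - dispersion) / dispersion
    p = np.where(
        (phi <= 0) | (phi >= 1),
        phi,
        rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)),
    )
    return rng.binomial(n, p)


def simulate_editing_counts(
    gt: GenotypeTable,
    truth: SimTruth,
    cfg: CohortConfig,
    tissue: str,
    mirna_levels: Mapping[str, Mapping[str, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> SiteCounts:
    """Draw A/G read counts for every site of the truth in one tissue.

    Totals are Poisson(coverage_mean); edited reads are beta-binomial at
    the (possibly degradation-distorted) latent editing level.
    Heterozygotes at the causal SNP are split into haplotype-resolved
    counts whose read shares follow the surviving transcript fractions,
    so the allelic sub-counts sum to the sample totals by construction.
    """
    if tissue not in cfg.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    if rng is None:
        rng = cfg.tissue_rng(tissue, stream=1)
    enzyme = cfg.enzyme_scalar[tissue]
    n_samp = gt.n_samples
    a_rows, g_rows, allelic_rows = [], [], []
    for st in truth:
        d_eff = _effective_d(st, tissue, mirna_levels)
        phi_s, _, hap_detail = latent_phi_and_expression(st, gt, enzyme, d_eff)
        total = rng.poisson(cfg.coverage_mean, size=n_samp)
        g_cnt = np.zeros(n_samp, dtype=int)
        j = gt.snp_index(st.snp)
        dos = gt.dosage[j]
        hom_mask = dos != 1
        g_cnt[hom_mask] = _betabin_draw(
            rng, total[hom_mask], phi_s[hom_mask], cfg.dispersion
        )
        for i, (ppr, ppa, er, ea) in hap_detail.items():
            w_ref = er / (er + ea)
            n_ref = rng.binomial(total[i], w_ref)
            n_alt = total[i] - n_ref
            g_ref = int(_betabin_draw(rng, n_ref, ppr, cfg.dispersion))
            g_alt = int(_betabin_draw(rng, n_alt, ppa, cfg.dispersion))
            g_cnt[i] = g_ref + g_alt
            allelic_rows.append(
                (st.site, st.snp, gt.samples[i], g_ref, int(n_ref), g_alt, int(n_alt))
            )
        a_rows.append(total - g_cnt)
        g_rows.append(g_cnt)
    sites = truth.site_table()
    a = pd.DataFrame(np.array(a_rows), index=sites.index, columns=gt.samples)
    g = pd.DataFrame(np.array(g_rows), index=sites.index, columns=gt.samples)
    allelic = pd.DataFrame(
        allelic_rows,
        columns=["site", "snp", "sample", "g_ref", "n_ref", "g_alt", "n_alt"],
    )
    return SiteCounts(sites=sites, a=a, g=g, allelic=allelic)


def simulate_expression(
    gt: GenotypeTable,
    truth: SimTruth,
    cfg: CohortConfig,
    tissue: str,
    mirna_levels: Mapping[str, Mapping[str, float]] | None = None,
    baseline_expr: float = 100.0,
    noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Genes x samples expression matrix (TPM-like) for one tissue.

    A gene coupled to a miRNA keeps only the surviving transcript fraction
    E = 1 - d_eff * (targeted fraction), where d_eff is the degradation
    rate scaled by the tissue's normalised miRNA level; multiplicative
    log-normal noise is applied throughout.  Uncoupled genes get noise
    only — their expression is independent of genotype.
    """
    if tissue not in cfg.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    if rng is None:
        rng = cfg.tissue_rng(tissue, stream=2)
    enzyme = cfg.enzyme_scalar[tissue]
    rows, genes = [], []
    for st in truth:
        d_eff = _effective_d(st, tissue, mirna_levels)
        _, e_samp, _ = latent_phi_and_expression(st, gt, enzyme, d_eff)
        noise = rng.lognormal(0.0, noise_sd, size=gt.n_samples)
        rows.append(baseline_expr * e_samp * noise)
        genes.append(st.gene)
    return pd.DataFrame(np.array(rows), index=pd.Index(genes, name="gene"),
                        columns=gt.samples)


def expected_phi_by_genotype(
    st: SiteTruth, enzyme: float = 1.0, d_eff: float = 0.0
) -> np.ndarray:
    """Expected observed Phi per genotype class (0, 1, 2), degradation included."""
    target = st.mirna.target_version if st.mirna else "unedited"
    eta0 = logit(st.baseline_phi)
    out = []
    es = enzyme * st.true_slope
    for g in (0, 1, 2):
        if g == 1:
            phis = np.array([expit(eta0 + es / 2.0), expit(eta0 + 3.0 * es / 2.0)])
            pp, ee = degradation_model(phis, d_eff, target)
            out.append(float(np.sum(pp * ee) / np.sum(ee)))
        else:
            pp, _ = degradation_model(expit(eta0 + enzyme * st.true_slope * g), d_eff, target)
            out.append(float(pp))
    return np.array(out)


def linearized_slope(
    st: SiteTruth, maf: float, enzyme: float = 1.0, d_eff: float = 0.0
) -> float:
    """Large-n OLS slope implied by the logit-scale truth under HWE.

    The edQTL regression is linear on the raw Phi scale while the
    generative effect is logit-additive, so the recoverable quantity is
    Cov(Phi(G), G) / Var(G) with G ~ Binomial(2, maf).
    """
    f = maf
    w = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    g = np.array([0.0, 1.0, 2.0])
    phi = expected_phi_by_genotype(st, enzyme, d_eff)
    gbar = np.sum(w * g)
    var_g = np.sum(w * (g - gbar) ** 2)
    cov = np.sum(w * (g - gbar) * (phi - np.sum(w * phi)))
    return float(cov / var_g)


# --- planted UTR sequences for editing-specific targeting ---------------

def plant_utr(
    mirna: MirnaRecord,
    version: Literal["unedited", "edited"],
    seed: int = 0,
    length: int = 120,
) -> tuple[str, int]:
    """Random 3'-UTR sequence with a planted editing-specific seed site.

    For ``version='edited'`` the seed complement carries a G that is
    replaced by A in the reference sequence: the match only exists after
    A-to-I editing.  For ``version='unedited'`` the complement carries an
    A at the editing position, so editing destroys the match.  Returns
    (utr_seq, edit_pos 1-based) verified against the classifier; raises if
    the miRNA seed complement lacks the required base.
    """
    rng = np.random.default_rng(seed)
    site8 = revcomp_rna(mirna.seq[1:8]) + "A"  # 8mer site on the target
    want = "G" if version == "edited" else "A"
    positions = [i for i, c in enumerate(site8[:7]) if c == want]
    if not positions:
        raise ValueError(
            f"seed complement {site8[:7]} has no {want}; pick another miRNA"
        )
    for _ in range(200):
        bases = rng.choice(list("ACGU"), size=length)
        seq = "".join(bases)
        insert_at = int(rng.integers(10, length - 20))
        k = positions[int(rng.integers(len(positions)))]
        planted = site8 if version == "unedited" else (
            site8[:k] + "A" + site8[k + 1 :]
        )
        if version == "unedited":
            # reference carries the match; edit the A inside the seed span
            utr = seq[:insert_at] + planted + seq[insert_at + len(planted):]
            edit_pos = insert_at + k + 1
        else:
            utr = seq[:insert_at] + planted + seq[insert_at + len(planted):]
            edit_pos = insert_at + k + 1
        try:
            cls = editing_specific_target(utr, edit_pos, mirna)
        except ValueError:
            continue
        if cls.version == version:
            return utr, edit_pos
    raise RuntimeError("failed to plant an editing-specific UTR site")
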