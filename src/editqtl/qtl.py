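"""Cis edQTL mapping and related statistics.

Editing levels are regressed on allele dosage (0/1/2) with ordinary least
squares inside a 400-kb window centred on the editing site; the lead SNP
is the closest SNP attaining the minimum p value.  The module also holds
the permutation-based FDR threshold, the genotype-by-tissue interaction
likelihood-ratio test, the non-linearity statistic comparing a quadratic
whole-data fit against the homozygote chord, cross-tissue effect-size
summaries, and genotypic LD utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW_BP = 400_000
DEFAULT_MAF_MIN = 0.05
DEFAULT_P_CUTOFF = 1e-5


@dataclass
class GenotypeTable:
    """Samples x SNPs alternate-allele dosages.

    ``dosage`` has shape (n_snps, n_samples) with entries in {0, 1, 2} or
    NaN for missing calls.  ``haplotypes``, when present, has shape
    (2, n_snps, n_samples) with 0/1 alt-allele indicators per haplotype
    and sums to ``dosage``.
    """

    samples: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(snp_id)
        return int(idx[0])


@dataclass
class QtlAssoc:
    """One site-SNP association from the linear dosage model."""

    site: object
    snp: object
    n: int
    slope: float
    intercept: float
    p: float
    distance: int
    se: float = float("nan")


@dataclass
class EdqtlResult:
    site: object
    lead: QtlAssoc | None
    assocs: pd.DataFrame
    is_edqtl: bool
    status: str  # "ok" | "untested"


def ols_assoc(phi: np.ndarray, dosage: np.ndarray):
    """OLS regression of Phi on dosage: (slope, intercept, p, n, se).

    Missing entries in either vector are dropped pairwise.  The p value is
    the two-sided t test on the slope with n - 2 degrees of freedom.  A
    constant dosage after filtering yields NaN slope and p (flagged, not
    raised); a constant phi gives slope 0 and p = 1.
    """
    phi = np.asarray(phi, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(phi) | np.isnan(dosage))
    y, x = phi[ok], dosage[ok]
    n = int(y.size)
    if n < 3:
        return np.nan, np.nan, np.nan, n, np.nan
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        return np.nan, np.nan, np.nan, n, np.nan
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    rss = float(np.sum(resid**2))
    if rss <= 0:
        # perfect fit: p underflows to 0 unless the slope itself is 0
        p = 1.0 if slope == 0 else 0.0
        return float(slope), float(intercept), p, n, 0.0
    se = np.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(slope), float(intercept), float(p), n, float(se)


def _ols_scan(phi: np.ndarray, dosages: np.ndarray):
    """Vectorised per-SNP OLS of one phi vector against many dosage rows.

    dosages: (m, n) with NaN for missing.  Returns arrays slope, se, p, n
    of length m; SNPs with constant dosage or fewer than 3 paired samples
    get NaN entries.
    """
    phi = np.asarray(phi, dtype=float)
    d = np.asarray(dosages, dtype=float)
    valid = ~np.isnan(phi)[None, :] & ~np.isnan(d)
    y = np.where(valid, phi[None, :], 0.0)
    x = np.where(valid, d, 0.0)
    n = valid.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = x.sum(axis=1) / n
        my = y.sum(axis=1) / n
        sxx = (x**2).sum(axis=1) - n * mx**2
        syy = (y**2).sum(axis=1) - n * my**2
        sxy = (x * y).sum(axis=1) - n * mx * my
        slope = sxy / sxx
        rss = syy - slope * sxy
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        t = slope / se
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
        p = np.where((rss == 0) & (slope != 0), 0.0, p)
        p = np.where((rss == 0) & (slope == 0), 1.0, p)
    bad = (n < 3) | (sxx <= 0)
    slope[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return slope, se, p, valid.sum(axis=1)


def map_edqtl(
    site,
    site_chrom: str,
    site_pos: int,
    phi_row: np.ndarray,
    gt: GenotypeTable,
    window_bp: int = DEFAULT_WINDOW_BP,
    maf_min: float = DEFAULT_MAF_MIN,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> EdqtlResult:
    """Scan SNPs in the cis window around one editing site.

    Tests every SNP with MAF >= maf_min within window_bp centred at the
    site (i.e. +/- window_bp/2).  Lead SNP: among SNPs attaining the
    minimum p, the one nearest the site; ties on distance break to the
    lower genomic coordinate.  The site is called an edQTL when the lead
    p value is <= p_cutoff.  phi_row must already carry NaN for samples
    masked by the coverage filter.
    """
    half = window_bp // 2
    in_window = (
        (gt.chrom == site_chrom)
        & (gt.pos >= site_pos - half)
        & (gt.pos <= site_pos + half)
    )
    maf = gt.maf()
    testable = in_window & (maf >= maf_min)
    idx = np.flatnonzero(testable)
    if idx.size == 0:
        return EdqtlResult(site, None, pd.DataFrame(), False, "untested")
    slope, se, p, n = _ols_scan(phi_row, gt.dosage[idx])
    dist = np.abs(gt.pos[idx] - site_pos)
    assocs = pd.DataFrame(
        {
            "site": site,
            "snp": gt.snp_ids[idx],
            "pos": gt.pos[idx],
            "distance": dist,
            "slope": slope,
            "se": se,
            "p": p,
            "n": n,
        }
    )
    ok = assocs.dropna(subset=["p"])
    if ok.empty:
        return EdqtlResult(site, None, assocs, False, "untested")
    pmin = ok["p"].min()
    at_min = ok[ok["p"] == pmin]
    at_min = at_min.sort_values(["distance", "pos"], kind="stable")
    row = at_min.iloc[0]
    lead_idx = idx[assocs.index.get_loc(row.name)]
    s, b, pv, nn, sev = ols_assoc(phi_row, gt.dosage[lead_idx])
    lead = QtlAssoc(
        site=site,
        snp=row["snp"],
        n=int(nn),
        slope=float(s),
        intercept=float(b),
        p=float(pv),
        distance=int(row["distance"]),
        se=float(sev),
    )
    return EdqtlResult(site, lead, assocs, bool(pv <= p_cutoff), "ok")


def map_edqtl_all(
    phi: pd.DataFrame,
    sites: pd.DataFrame,
    gt: GenotypeTable,
    **kwargs,
) -> dict:
    """map_edqtl over every row of a Phi matrix; returns site -> EdqtlResult."""
    order = [phi.columns.get_loc(s) for s in gt.samples]
    results = {}
    for site in phi.index:
        row = phi.loc[site].to_numpy()[order]
        results[site] = map_edqtl(
            site, sites.loc[site, "chrom"], int(sites.loc[site, "pos"]), row, gt, **kwargs
        )
    return results


def window_assoc_stats(
    y: np.ndarray,
    gt: GenotypeTable,
    site_chrom: str,
    site_pos: int,
    window_bp: int = DEFAULT_WINDOW_BP,
    maf_min: float = DEFAULT_MAF_MIN,
) -> pd.DataFrame:
    """Per-SNP OLS summary statistics (snp, beta, se, p, n) in a cis window.

    Used both for edQTL summary statistics (y = editing levels) and eQTL
    summary statistics (y = expression of the site's gene), keeping the
    two traits aligned on the same SNP set for colocalization.
    """
    half = window_bp // 2
    maf = gt.maf()
    testable = (
        (gt.chrom == site_chrom)
        & (gt.pos >= site_pos - half)
        & (gt.pos <= site_pos + half)
        & (maf >= maf_min)
    )
    idx = np.flatnonzero(testable)
    if idx.size == 0:
        return pd.DataFrame(columns=["snp", "beta", "se", "p", "n"])
    slope, se, p, n = _ols_scan(np.asarray(y, dtype=float), gt.dosage[idx])
    return pd.DataFrame(
        {"snp": gt.snp_ids[idx], "beta": slope, "se": se, "p": p, "n": n}
    )


def _min_window_p(phi: pd.DataFrame, sites: pd.DataFrame, gt: GenotypeTable,
                  window_bp: int, maf_min: float) -> np.ndarray:
    maf = gt.maf()
    half = window_bp // 2
    out = np.full(len(phi.index), np.nan)
    phi_arr = phi.to_numpy()
    for i, site in enumerate(phi.index):
        site_chrom = sites.loc[site, "chrom"]
        site_pos = int(sites.loc[site, "pos"])
        testable = (
            (gt.chrom == site_chrom)
            & (gt.pos >= site_pos - half)
            & (gt.pos <= site_pos + half)
            & (maf >= maf_min)
        )
        idx = np.flatnonzero(testable)
        if idx.size == 0:
            continue
        _, _, p, _ = _ols_scan(phi_arr[i], gt.dosage[idx])
        if np.isfinite(p).any():
            out[i] = np.nanmin(p)
    return out


def permutation_threshold(
    phi: pd.DataFrame,
    sites: pd.DataFrame,
    gt: GenotypeTable,
    B: int = 5,
    target_fdr: float = 0.10,
    window_bp: int = DEFAULT_WINDOW_BP,
    maf_min: float = DEFAULT_MAF_MIN,
    seed: int = 0,
    _permutations: Sequence[np.ndarray] | None = None,
):
    """Permutation-calibrated p-value cutoff at a target FDR.

    Sample labels of the genotype table are permuted jointly across SNPs
    (preserving LD) B times; each site's minimum window p value is
    recomputed per permutation.  For each observed minimum p value t,
    the empirical FDR is the mean permuted count of sites with min p <= t
    divided by the observed count; the returned threshold is the largest
    t with FDR <= target_fdr, or None when no t qualifies.

    ``_permutations`` injects explicit sample orderings (testing hook).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    phi = phi[gt.samples]
    obs = _min_window_p(phi, sites, gt, window_bp, maf_min)
    obs = obs[np.isfinite(obs)]
    if obs.size == 0:
        return None
    rng = np.random.default_rng(seed)
    perm_minp = []
    for b in range(B):
        if _permutations is not None:
            order = np.asarray(_permutations[b])
        else:
            order = rng.permutation(gt.n_samples)
        gt_perm = GenotypeTable(
            samples=gt.samples,
            snp_ids=gt.snp_ids,
            chrom=gt.chrom,
            pos=gt.pos,
            dosage=gt.dosage[:, order],
        )
        mp = _min_window_p(phi, sites, gt_perm, window_bp, maf_min)
        perm_minp.append(mp[np.isfinite(mp)])
    grid = np.sort(obs)
    best = None
    for t in grid:
        n_obs = float((obs <= t).sum())
        n_perm = float(np.mean([(mp <= t).sum() for mp in perm_minp]))
        if n_obs > 0 and n_perm / n_obs <= target_fdr:
            best = float(t)
    return best


@dataclass
class InteractionFit:
    """Genotype-by-tissue interaction fit.

    Model: Phi = mu + alpha*genotype + beta*tissue + gamma*genotype*tissue,
    with the binary tissue factor encoding muscle vs non-muscle.  The LRT
    compares the fit with and without gamma (chi-square, 1 df).
    """

    mu: float
    alpha: float
    beta: float
    gamma: float
    resid_var: float
    lrt: float
    p: float
    n: int
    status: str = "ok"


def interaction_lrt(phi, dosage, tissue_flag) -> InteractionFit:
    """LRT for a genotype x tissue interaction on editing levels.

    Gaussian maximum-likelihood fits of the full model (with interaction)
    and the reduced additive model; statistic 2*delta-loglik reduces to
    n * ln(RSS_reduced / RSS_full), referred to chi-square with 1 df.
    """
    phi = np.asarray(phi, dtype=float)
    g = np.asarray(dosage, dtype=float)
    t = np.asarray(tissue_flag, dtype=float)
    ok = ~(np.isnan(phi) | np.isnan(g) | np.isnan(t))
    phi, g, t = phi[ok], g[ok], t[ok]
    n = phi.size
    for flag in (0.0, 1.0):
        sub = g[t == flag]
        if sub.size == 0 or np.unique(sub).size < 2:
            return InteractionFit(*[np.nan] * 5, np.nan, np.nan, n, "singular")
    X_full = np.column_stack([np.ones(n), g, t, g * t])
    X_red = X_full[:, :3]
    beta_full, rss_full = _lstsq_rss(X_full, phi)
    beta_red, rss_red = _lstsq_rss(X_red, phi)
    rss_full = max(rss_full, 1e-300)
    lrt = max(0.0, n * np.log(max(rss_red, rss_full) / rss_full))
    p = float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    return InteractionFit(
        mu=float(beta_full[0]),
        alpha=float(beta_full[1]),
        beta=float(beta_full[2]),
        gamma=float(beta_full[3]),
        resid_var=float(rss_full / n),
        lrt=float(lrt),
        p=p,
        n=int(n),
    )


def _lstsq_rss(X, y):
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return beta, rss


@dataclass
class NonlinearityResult:
    """Deviation of heterozygote editing from the homozygote chord.

    ``shift`` is the quadratic whole-data fit evaluated at dosage 1 minus
    the homozygote-only line evaluated at dosage 1; a miRNA degrading the
    unedited transcripts pushes the shift positive, degrading the edited
    transcripts pushes it negative.
    """

    quad_coef: np.ndarray  # highest degree first
    hom_coef: np.ndarray
    shift: float
    lrt: float
    p: float
    status: str = "ok"


def nonlinearity(phi, dosage) -> NonlinearityResult:
    """Quadratic-vs-linear non-linearity statistic for one edQTL.

    Requires all three genotype classes with at least two samples in each
    homozygote class; otherwise flagged untestable.  The p value is a
    Gaussian LRT of the quadratic against the linear whole-data model,
    chi-square with 1 df.
    """
    phi = np.asarray(phi, dtype=float)
    g = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(phi) | np.isnan(g))
    phi, g = phi[ok], g[ok]
    counts = {k: int((g == k).sum()) for k in (0, 1, 2)}
    if counts[1] < 1 or counts[0] < 2 or counts[2] < 2:
        return NonlinearityResult(
            np.full(3, np.nan), np.full(2, np.nan), np.nan, np.nan, np.nan,
            "missing genotype class",
        )
    quad = np.polyfit(g, phi, 2)
    lin = np.polyfit(g, phi, 1)
    hom_mask = g != 1
    hom = np.polyfit(g[hom_mask], phi[hom_mask], 1)
    shift = float(np.polyval(quad, 1.0) - np.polyval(hom, 1.0))
    n = phi.size
    rss_quad = float(np.sum((phi - np.polyval(quad, g)) ** 2))
    rss_lin = float(np.sum((phi - np.polyval(lin, g)) ** 2))
    rss_quad = max(rss_quad, 1e-300)
    lrt = max(0.0, n * np.log(max(rss_lin, rss_quad) / rss_quad))
    p = float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    return NonlinearityResult(quad, hom, shift, float(lrt), p)


def effect_size_matrix(
    per_tissue: Mapping[str, Mapping[object, float]],
    complete_only: bool = False,
) -> pd.DataFrame:
    """Sites x tissues matrix of lead edQTL slopes.

    ``per_tissue`` maps tissue -> {site -> slope} for sites that passed
    filters and had a computable slope in that tissue.  With
    ``complete_only`` the matrix is restricted to sites measurable in
    every tissue.
    """
    mat = pd.DataFrame(per_tissue)
    if complete_only:
        mat = mat.dropna(axis=0, how="any")
    return mat


def cv_filter(slope_matrix: pd.DataFrame, cv_min: float = 1.0) -> pd.DataFrame:
    """Flag sites with large cross-tissue variation in effect size.

    CV = sd / mean of the per-tissue slopes (sample sd, ddof=1); sites with
    |CV| >= cv_min are flagged.  A zero mean leaves the CV undefined and is
    flagged separately.
    """
    mean = slope_matrix.mean(axis=1)
    sd = slope_matrix.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    undefined = mean == 0
    flagged = (~undefined) & (cv.abs() >= cv_min)
    return pd.DataFrame(
        {"cv": cv.where(~undefined), "flagged": flagged, "undefined": undefined}
    )


def enzyme_correlation(slopes, enzyme_levels, r2_min: float = 0.5):
    """Squared Pearson correlation between per-tissue slopes and enzyme level.

    Returns (R2, flagged) with the flag set at R2 >= r2_min; NaN when either
    vector has zero variance or fewer than 3 tissues overlap.
    """
    x = np.asarray(slopes, dtype=float)
    y = np.asarray(enzyme_levels, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), False
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r * r)
    return r2, bool(r2 >= r2_min)


def ld_r2(dosage1, dosage2) -> float:
    """Genotypic LD: squared Pearson correlation of allele dosages."""
    x = np.asarray(dosage1, dtype=float)
    y = np.asarray(dosage2, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def gwas_link(
    lead_snps: Mapping[object, str],
    catalog: pd.DataFrame,
    gt: GenotypeTable,
    r2_min: float = 0.8,
):
    """Link lead edQTL/ASED SNPs to GWAS catalog SNPs in high LD.

    ``catalog`` needs columns ``snp`` and ``trait``.  Catalog SNPs absent
    from the genotype table are skipped and counted.  Returns a records
    DataFrame (site, lead_snp, gwas_snp, trait, r2) with r2 > r2_min, plus
    the number of skipped catalog SNPs.
    """
    known = set(gt.snp_ids.tolist())
    skipped = int((~catalog["snp"].isin(known)).sum())
    cat = catalog[catalog["snp"].isin(known)]
    rows = []
    for site, lead in lead_snps.items():
        if lead not in known:
            continue
        d1 = gt.dosage[gt.snp_index(lead)]
        for _, rec in cat.iterrows():
            r2 = ld_r2(d1, gt.dosage[gt.snp_index(rec["snp"])])
            if np.isfinite(r2) and r2 > r2_min:
                rows.append((site, lead, rec["snp"], rec["trait"], r2))
    records = pd.DataFrame(
        rows, columns=["site", "lead_snp", "gwas_snp", "trait", "r2"]
    )
    return records, skipped
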