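"""Allele-specific RNA editing (ASED).

In individuals heterozygous for a cis SNP, reads can be assigned to the
two haplotypes and the editing level Phi computed per allele.  The two
alleles of each individual form a matched pair; individuals sharing the
heterozygous SNP are replicates.  A binomial likelihood with a
per-individual baseline and a shared allele effect delta (on the logit
scale) is fit by profile maximum likelihood and tested with a
likelihood-ratio test; per-allele confidence intervals come from
inverting the binomial likelihood ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

ALLELIC_COLUMNS = ["site", "snp", "sample", "g_ref", "n_ref", "g_alt", "n_alt"]

_DELTA_BOUND = 15.0  # logit-scale search bound; hit => complete separation


def _binom_loglik(g, n, p):
    return special.xlogy(g, p) + special.xlogy(n - g, 1.0 - p)


def allelic_phi_ci(g: int, n: int, level: float = 0.95):
    """Binomial likelihood-ratio confidence interval for Phi.

    Returns (phi_hat, lo, hi) where the interval is the set of p with
    2*[loglik(phi_hat) - loglik(p)] <= chi2_1(level), found by bisection.
    The boundary cases g = 0 and g = n pin lo = 0 and hi = 1 exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= g <= n:
        raise ValueError("g must lie in [0, n]")
    phat = g / n
    crit = stats.chi2.ppf(level, 1) / 2.0
    ll_hat = _binom_loglik(g, n, phat) if 0 < phat < 1 else 0.0
    if phat in (0.0, 1.0):
        ll_hat = 0.0

    def deficit(p):
        return (ll_hat - _binom_loglik(g, n, p)) - crit

    if g == 0:
        lo = 0.0
    else:
        lo = optimize.brentq(deficit, 1e-12, phat, xtol=1e-9)
    if g == n:
        hi = 1.0
    else:
        hi = optimize.brentq(deficit, phat, 1.0 - 1e-12, xtol=1e-9)
    return phat, float(lo), float(hi)


def ased_filter(allelic: pd.DataFrame, min_phi: float = 0.01, min_individuals: int = 3):
    """Individual-level usability filter for one site-SNP pair.

    Keeps individuals with non-zero coverage on both alleles and pooled
    editing level (g_ref+g_alt)/(n_ref+n_alt) >= min_phi.  The pair is
    testable when at least ``min_individuals`` remain.
    Returns (kept DataFrame, testable flag).
    """
    ac = allelic
    cov = (ac["n_ref"] > 0) & (ac["n_alt"] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (ac["g_ref"] + ac["g_alt"]) / (ac["n_ref"] + ac["n_alt"]).replace(0, np.nan)
    keep = cov & (pooled >= min_phi)
    kept = ac[keep.fillna(False)]
    return kept, len(kept) >= min_individuals


@dataclass
class AsedResult:
    """Paired allele-specific editing test for one site-SNP pair."""

    site: object
    snp: object
    n_individuals: int
    phi_ref: float  # mean allelic Phi, reference haplotype
    phi_alt: float
    delta: float  # shared allele effect on the logit scale (ref minus alt)
    lrt: float
    p: float
    per_individual: pd.DataFrame | None = None
    boundary: bool = False
    q: float = float("nan")


def _profile_mu(gr, nr, ga, na, delta):
    """Per-individual Newton maximisation of mu at fixed delta.

    Model: Phi_ref = expit(mu + delta/2), Phi_alt = expit(mu - delta/2);
    the binomial log-likelihood is concave in mu, so Newton from the
    pooled logit converges in a handful of steps.
    """
    pooled = (gr + ga + 0.5) / (nr + na + 1.0)
    mu = special.logit(pooled)
    for _ in range(50):
        pr = special.expit(mu + delta / 2.0)
        pa = special.expit(mu - delta / 2.0)
        grad = (gr - nr * pr) + (ga - na * pa)
        hess = -(nr * pr * (1 - pr) + na * pa * (1 - pa))
        step = grad / np.where(hess == 0, -1.0, hess)
        mu = mu - step
        mu = np.clip(mu, -30.0, 30.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return mu


def _loglik_at(gr, nr, ga, na, mu, delta):
    pr = special.expit(mu + delta / 2.0)
    pa = special.expit(mu - delta / 2.0)
    return float(np.sum(_binom_loglik(gr, nr, pr) + _binom_loglik(ga, na, pa)))


def paired_ased_test(allelic: pd.DataFrame, ci_level: float = 0.95) -> AsedResult:
    """Paired likelihood-ratio test for allele-specific editing.

    Requires >= 3 usable individuals (apply :func:`ased_filter` first).
    delta > 0 means the reference haplotype is edited more than the
    alternate one.  Complete separation (an allele stuck at 0% or 100%
    across individuals) drives delta to the search boundary and is
    flagged.
    """
    ac = allelic
    if len(ac) < 3:
        raise ValueError("paired ASED test requires >= 3 individuals")
    gr = ac["g_ref"].to_numpy(dtype=float)
    nr = ac["n_ref"].to_numpy(dtype=float)
    ga = ac["g_alt"].to_numpy(dtype=float)
    na = ac["n_alt"].to_numpy(dtype=float)

    # Null: delta = 0, per-individual MLE is the pooled proportion.
    pooled = (gr + ga) / (nr + na)
    ll0 = float(np.sum(_binom_loglik(gr + ga, nr + na, np.clip(pooled, 1e-300, 1.0))))

    def neg_profile(delta):
        mu = _profile_mu(gr, nr, ga, na, delta)
        return -_loglik_at(gr, nr, ga, na, mu, delta)

    res = optimize.minimize_scalar(
        neg_profile, bounds=(-_DELTA_BOUND, _DELTA_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    delta_hat = float(res.x)
    ll1 = -float(res.fun)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    # complete separation: an allele pinned at 0% or 100% across individuals
    boundary = bool(
        gr.sum() == 0 or ga.sum() == 0 or (gr == nr).all() or (ga == na).all()
        or abs(delta_hat) >= _DELTA_BOUND - 0.05
    )

    per_ind = []
    for i in range(len(ac)):
        pr_hat, pr_lo, pr_hi = allelic_phi_ci(int(gr[i]), int(nr[i]), ci_level)
        pa_hat, pa_lo, pa_hi = allelic_phi_ci(int(ga[i]), int(na[i]), ci_level)
        per_ind.append(
            (ac["sample"].iloc[i] if "sample" in ac else i,
             pr_hat, pr_lo, pr_hi, pa_hat, pa_lo, pa_hi)
        )
    per_ind = pd.DataFrame(
        per_ind,
        columns=["sample", "phi_ref", "ref_lo", "ref_hi", "phi_alt", "alt_lo", "alt_hi"],
    )
    return AsedResult(
        site=ac["site"].iloc[0] if "site" in ac else None,
        snp=ac["snp"].iloc[0] if "snp" in ac else None,
        n_individuals=len(ac),
        phi_ref=float(np.mean(gr / nr)),
        phi_alt=float(np.mean(ga / na)),
        delta=delta_hat,
        lrt=float(lrt),
        p=p,
        per_individual=per_ind,
        boundary=boundary,
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def ased_scan(
    allelic: pd.DataFrame,
    min_phi: float = 0.01,
    min_individuals: int = 3,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Run the paired test over every (site, snp) pair in a long table.

    Applies the usability filter per pair, tests the testable pairs, and
    controls the FDR across pairs with Benjamini-Hochberg; significance at
    q <= fdr.
    """
    rows = []
    for (site, snp), grp in allelic.groupby(["site", "snp"], sort=True):
        kept, testable = ased_filter(grp, min_phi, min_individuals)
        if not testable:
            continue
        r = paired_ased_test(kept)
        rows.append((site, snp, r.n_individuals, r.phi_ref, r.phi_alt,
                     r.delta, r.p, r.boundary))
    out = pd.DataFrame(
        rows,
        columns=["site", "snp", "n", "phi_ref", "phi_alt", "delta", "p", "boundary"],
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] <= fdr
    return out
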