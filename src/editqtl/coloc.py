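"""Two-trait Bayesian colocalization from per-SNP summary statistics.

Each SNP's evidence of association with a trait is summarised by a
Wakefield approximate Bayes factor computed from the effect estimate and
its standard error.  Under the single-causal-variant assumption the locus
then falls into one of five hypotheses: no association (H0), trait 1 only
(H1), trait 2 only (H2), two distinct causal variants (H3), or one shared
causal variant (H4).  Posterior probabilities PP0-PP4 are prior-weighted,
normalised sums of per-SNP Bayes factors, accumulated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats

#: prior sd^2 of the causal effect for a quantitative trait (sd 0.15)
DEFAULT_W = 0.15**2
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5


def wakefield_abf(beta, se, W: float = DEFAULT_W):
    """Log approximate Bayes factor for one SNP-trait association.

    With z = beta/se, V = se^2 and shrinkage r = W/(V+W):
    log ABF = 0.5*log(1-r) + r*z^2/2.  Vectorised over beta/se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if W <= 0:
        raise ValueError("prior variance W must be positive")
    z = beta / se
    V = se**2
    r = W / (V + W)
    out = 0.5 * np.log(1.0 - r) + r * z**2 / 2.0
    return float(out) if out.ndim == 0 else out


def zscore_from_p(p, sign=None):
    """|z| recovered from a two-sided p value; optional sign restores direction."""
    p = np.asarray(p, dtype=float)
    z = stats.norm.isf(p / 2.0)
    if sign is not None:
        z = z * np.sign(sign)
    return z


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    labf1,
    labf2,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> ColocResult:
    """Combine per-SNP log ABFs of two traits into PP0-PP4.

    H1 sums ABFs of trait 1, H2 of trait 2, H4 the elementwise products
    (shared causal SNP), and H3 all ordered pairs of distinct SNPs —
    computed in log space as sum1*sum2 minus the diagonal.  Posteriors
    are proportional to (1, p1*S1, p2*S2, p1*p2*S3, p12*S4).
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("log ABF vectors must be aligned and equal length")
    if l1.size == 0:
        raise ValueError("need at least one SNP")
    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    lh3 = _logdiffexp(ls1 + ls2, ls12) if l1.size > 1 else -np.inf
    logw = np.array(
        [
            0.0,
            np.log(p1) + ls1,
            np.log(p2) + ls2,
            np.log(p1) + np.log(p2) + lh3,
            np.log(p12) + ls12,
        ]
    )
    pp = np.exp(logw - logsumexp(logw))
    pp = pp / pp.sum()
    return ColocResult(*pp.tolist(), n_snps=int(l1.size), p1=p1, p2=p2, p12=p12)


def coloc_from_assoc(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    W1: float = DEFAULT_W,
    W2: float = DEFAULT_W,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> ColocResult:
    """Colocalize two traits from per-SNP summary statistics.

    Each frame needs columns ``snp``, ``beta``, ``se``; SNPs are aligned
    by id and unshared SNPs dropped.  When ``beta``/``se`` are missing, a
    ``p`` column (with optional ``sign``) is converted to a z score with
    unit standard error, and the prior variance for that trait switches to
    1 on the z scale (a unit-information-style prior), since the
    effect-scale default W would shrink z-based evidence to nothing.
    """
    s1, fb1 = _prepare_stats(stats1)
    s2, fb2 = _prepare_stats(stats2)
    if fb1:
        W1 = 1.0
    if fb2:
        W2 = 1.0
    merged = s1.merge(s2, on="snp", suffixes=("_1", "_2"))
    merged = merged.dropna(subset=["beta_1", "se_1", "beta_2", "se_2"])
    if len(merged) < 1:
        raise ValueError("no shared SNPs with usable statistics")
    labf1 = wakefield_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), W1)
    labf2 = wakefield_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), W2)
    return coloc_posteriors(labf1, labf2, p1, p2, p12)


def _prepare_stats(df: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    out = df.copy()
    fallback = False
    if "beta" not in out or "se" not in out or out["beta"].isna().all():
        if "p" not in out:
            raise ValueError("summary stats need beta+se or p")
        sign = out["sign"] if "sign" in out else None
        z = zscore_from_p(out["p"].to_numpy(), None if sign is None else sign.to_numpy())
        out["beta"] = z
        out["se"] = 1.0
        fallback = True
    return out[["snp", "beta", "se"]], fallback
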