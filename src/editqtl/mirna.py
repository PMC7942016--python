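"""miRNA targeting of edited transcripts and its QTL consequences.

A-to-I editing inside a 3'-UTR can create or destroy a miRNA seed match
(inosine pairs like guanosine), so a miRNA may degrade only the edited or
only the unedited transcript pool.  This module provides: a proxy for
miRNA abundance from reads over the primary-transcript cleavage product;
a canonical seed-match scanner (8mer, 7mer-m8, 7mer-A1); classification
of editing-specific target sites; the steady-state degradation model that
converts an edQTL into an eQTL; forward simulation of edQTL/eQTL panels;
and a beta-binomial differential-editing test for miRNA perturbation
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .ased import bh_fdr

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass
class MirnaRecord:
    """A mature miRNA, its genomic primary-transcript interval, and per-tissue proxy levels."""

    name: str
    seq: str  # mature sequence 5'->3', RNA alphabet
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    proxy: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = normalize_rna(self.seq)
        if len(self.seq) < 8:
            raise ValueError("mature miRNA sequence must be >= 8 nt")


def normalize_rna(seq: str) -> str:
    """Uppercase and map T->U; rejects non-ACGU characters."""
    s = seq.upper().replace("T", "U")
    if set(s) - set("ACGU"):
        raise ValueError(f"non-ACGU characters in sequence: {seq!r}")
    return s


def revcomp_rna(seq: str) -> str:
    return normalize_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


def proxy_expression(interval_counts, totals):
    """Per-sample miRNA proxy: interval reads / total aligned, scaled so max = 1.

    Mirrors quantifying mature miRNA from poly-A RNA-seq via reads over
    the pri-miRNA cleavage product.  All-zero rates are returned as zeros
    (flagged undefined by the caller).
    """
    ic = np.asarray(interval_counts, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if np.any(tot <= 0):
        raise ValueError("total aligned read counts must be positive")
    rate = ic / tot
    top = rate.max()
    if top == 0:
        return np.zeros_like(rate)
    return rate / top


MatchType = Literal["8mer", "7mer-m8", "7mer-A1"]


@dataclass(frozen=True)
class SeedMatch:
    """A canonical miRNA seed-match site on a target sequence (1-based span)."""

    match_type: MatchType
    start: int
    end: int

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def seed_match(target_seq: str, mirna: MirnaRecord) -> list[SeedMatch]:
    """Scan a target (5'->3') for canonical seed matches to one miRNA.

    Site classes, on the target read 5'->3':
      7mer-m8 : exact Watson-Crick complement of miRNA positions 2-8;
      7mer-A1 : complement of positions 2-7 followed by an A;
      8mer    : complement of positions 2-8 followed by an A.
    Each start position is classified by the strongest class it supports
    (8mer > 7mer-m8 > 7mer-A1).  Only the given strand is scanned.
    """
    target = normalize_rna(target_seq)
    if len(target) < 7:
        return []
    m = mirna.seq
    seed7 = revcomp_rna(m[1:8])  # complements miRNA positions 2..8
    seed6 = revcomp_rna(m[1:7])  # complements miRNA positions 2..7
    matches: list[SeedMatch] = []
    L = len(target)
    for i in range(L - 6):
        if target[i : i + 7] == seed7:
            if i + 7 < L and target[i + 7] == "A":
                matches.append(SeedMatch("8mer", i + 1, i + 8))
            else:
                matches.append(SeedMatch("7mer-m8", i + 1, i + 7))
        elif target[i : i + 6] == seed6 and i + 6 < L and target[i + 6] == "A":
            matches.append(SeedMatch("7mer-A1", i + 1, i + 7))
    return matches


TargetVersion = Literal["unedited", "edited", "both", "neither"]


@dataclass
class TargetClassification:
    version: TargetVersion
    matches_unedited: list[SeedMatch]
    matches_edited: list[SeedMatch]


def editing_specific_target(
    utr_seq: str, edit_pos: int, mirna: MirnaRecord
) -> TargetClassification:
    """Classify whether a miRNA targets the edited or unedited transcript.

    The edited sequence substitutes G for A at ``edit_pos`` (1-based;
    inosine read as guanosine).  Only seed matches whose span covers the
    edited position count toward specificity: 'unedited'/'edited' when a
    covering match exists in exactly one version, 'both' when covering
    matches exist in both versions or the only matches lie elsewhere
    (identical in both versions), 'neither' when no match exists at all.
    """
    seq = normalize_rna(utr_seq)
    if not 1 <= edit_pos <= len(seq):
        raise ValueError("edit position outside the sequence")
    if seq[edit_pos - 1] != "A":
        raise ValueError("base at the editing position must be A (unedited reference)")
    edited = seq[: edit_pos - 1] + "G" + seq[edit_pos:]
    mu = seed_match(seq, mirna)
    me = seed_match(edited, mirna)
    cov_u = [x for x in mu if x.covers(edit_pos)]
    cov_e = [x for x in me if x.covers(edit_pos)]
    if cov_u and not cov_e:
        version: TargetVersion = "unedited"
    elif cov_e and not cov_u:
        version = "edited"
    elif cov_u and cov_e:
        version = "both"
    elif mu or me:
        version = "both"  # match away from the site: present in both versions
    else:
        version = "neither"
    return TargetClassification(version, mu, me)


@dataclass
class SimScenario:
    """Genotype-dependent baseline editing plus one miRNA degradation effect."""

    phi_by_genotype: Sequence[float]  # (Phi_0, Phi_1, Phi_2) before degradation
    d: float = 0.0
    target_version: Literal["unedited", "edited"] = "unedited"

    def __post_init__(self) -> None:
        phis = np.asarray(self.phi_by_genotype, dtype=float)
        if np.any((phis < 0) | (phis > 1)):
            raise ValueError("baseline Phi values must lie in [0, 1]")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("degradation rate d must lie in [0, 1]")


@dataclass
class SimResult:
    phi_observed: np.ndarray  # Phi' per genotype after degradation
    expression: np.ndarray  # relative steady-state transcript level per genotype


def degradation_model(phi, d: float, target_version: str = "unedited"):
    """Steady-state editing level and expression after miRNA degradation.

    A fraction d of the targeted transcript version is removed.  Targeting
    the unedited pool: E = Phi + (1-d)(1-Phi), Phi' = Phi / E.  Targeting
    the edited pool: E = (1-d)Phi + (1-Phi), Phi' = (1-d)Phi / E.
    E is the surviving transcript fraction relative to no degradation, and
    Phi'*E equals the surviving edited fraction identically.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("Phi must lie in [0, 1]")
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must lie in [0, 1]")
    if target_version == "unedited":
        E = phi + (1.0 - d) * (1.0 - phi)
        phi_prime = np.where(E > 0, phi / np.where(E > 0, E, 1.0), 1.0)
    elif target_version == "edited":
        E = (1.0 - d) * phi + (1.0 - phi)
        phi_prime = np.where(E > 0, (1.0 - d) * phi / np.where(E > 0, E, 1.0), 0.0)
    else:
        raise ValueError("target_version must be 'unedited' or 'edited'")
    return phi_prime, E


def run_scenario(scenario: SimScenario) -> SimResult:
    """Apply the degradation model to the three genotype classes."""
    phi_prime, E = degradation_model(
        scenario.phi_by_genotype, scenario.d, scenario.target_version
    )
    return SimResult(phi_observed=phi_prime, expression=E)


def simulate_qtl_panels(
    scenario: SimScenario,
    n_per_genotype: int = 50,
    coverage: int = 100,
    noise_sd: float = 0.05,
    baseline_expr: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw per-individual (Phi', expression) panels under a degradation scenario.

    Individuals are sampled per genotype class; observed Phi comes from
    binomial reads at the degraded editing level and expression carries
    multiplicative log-normal noise.  The output feeds the edQTL linear
    fit and the non-linearity statistic directly.
    """
    if n_per_genotype < 2:
        raise ValueError("need at least 2 individuals per genotype")
    rng = np.random.default_rng(rng)
    out = run_scenario(scenario)
    rows = []
    for g in (0, 1, 2):
        phi_g = out.phi_observed[g]
        e_g = out.expression[g]
        reads = rng.binomial(coverage, phi_g, size=n_per_genotype)
        phi_obs = reads / coverage
        expr = baseline_expr * e_g * rng.lognormal(0.0, noise_sd, size=n_per_genotype)
        for k in range(n_per_genotype):
            rows.append((g, phi_obs[k], expr[k]))
    return pd.DataFrame(rows, columns=["dosage", "phi", "expression"])


# --- differential editing under miRNA perturbation ----------------------

def _betabin_negll(g, n, p, rho):
    """Negative beta-binomial log-likelihood (binomial coefficient dropped).

    rho is the overdispersion correlation; rho -> 0 recovers the binomial.
    """
    if rho < 1e-8:
        return -float(np.sum(special.xlogy(g, p) + special.xlogy(n - g, 1 - p)))
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    ll = (
        special.gammaln(g + a)
        + special.gammaln(n - g + b)
        - special.gammaln(n + a + b)
        - special.gammaln(a)
        - special.gammaln(b)
        + special.gammaln(a + b)
    )
    return -float(np.sum(ll))


def _profile_p_nll(g, n, rho):
    """Minimum negative log-likelihood over the mean at fixed dispersion."""

    def f(lp):
        return _betabin_negll(g, n, special.expit(lp), rho)

    res = optimize.minimize_scalar(
        f, bounds=(-12.0, 12.0), method="bounded", options={"xatol": 1e-7}
    )
    return float(res.fun)


def _fit_shared_rho(groups):
    """Shared-dispersion MLE with group-specific means (profile likelihood).

    Returns (rho_hat, nll at the optimum).
    """

    def f(lr):
        rho = special.expit(lr)
        return sum(_profile_p_nll(g, n, rho) for g, n in groups)

    res = optimize.minimize_scalar(
        f,
        bounds=(special.logit(1e-6), special.logit(0.5)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(special.expit(res.x)), float(res.fun)


@dataclass
class DiffEditingResult:
    delta_phi: float  # pooled Phi_expt - pooled Phi_ctrl
    p: float
    lrt: float
    phi_ctrl: float
    phi_expt: float
    rho: float
    status: str = "ok"


def diff_editing_test(
    counts_ctrl: Iterable[tuple[int, int]],
    counts_expt: Iterable[tuple[int, int]],
) -> DiffEditingResult:
    """Beta-binomial likelihood-ratio test for a change in editing level.

    Replicates within a condition share a mean editing level; the two
    conditions share a dispersion, estimated once under the full
    (condition-specific means) model and held fixed while refitting the
    common-mean null — the LRT then compares one mean against two at that
    dispersion (chi-square, 1 df).  Estimating the dispersion jointly in
    both fits is markedly conservative at the few-replicate scale, which
    is why it is profiled out here.  delta_phi is the difference of
    pooled editing levels (experiment minus control).
    """
    ctrl = np.asarray(list(counts_ctrl), dtype=float)
    expt = np.asarray(list(counts_expt), dtype=float)
    if ctrl.size == 0 or expt.size == 0:
        raise ValueError("both conditions need at least one replicate")
    gc, nc = ctrl[:, 0], ctrl[:, 1]
    ge, ne = expt[:, 0], expt[:, 1]
    if np.any(gc > nc) or np.any(ge > ne):
        raise ValueError("edited reads cannot exceed total reads")
    if nc.sum() == 0 or ne.sum() == 0:
        return DiffEditingResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                                 "untestable")
    phi_c = gc.sum() / nc.sum()
    phi_e = ge.sum() / ne.sum()
    g_all = np.concatenate([gc, ge])
    n_all = np.concatenate([nc, ne])
    rho, nll1 = _fit_shared_rho([(gc, nc), (ge, ne)])
    nll0 = _profile_p_nll(g_all, n_all, rho)
    lrt = max(0.0, 2.0 * (nll0 - nll1))
    p = float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    return DiffEditingResult(
        delta_phi=float(phi_e - phi_c),
        p=p,
        lrt=float(lrt),
        phi_ctrl=float(phi_c),
        phi_expt=float(phi_e),
        rho=rho,
    )


def diff_editing_scan(
    table: pd.DataFrame,
    min_delta: float = 0.05,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential-editing test per site with BH FDR and effect-size gate.

    ``table`` is long form with columns site, condition ('control' or
    'experiment'), g, n.  A site is significant when |delta_phi| >=
    min_delta and q <= fdr.
    """
    rows = []
    for site, grp in table.groupby("site", sort=True):
        ctrl = grp[grp["condition"] == "control"][["g", "n"]].to_numpy()
        expt = grp[grp["condition"] == "experiment"][["g", "n"]].to_numpy()
        if len(ctrl) == 0 or len(expt) == 0:
            continue
        r = diff_editing_test(ctrl, expt)
        if r.status != "ok":
            continue
        rows.append((site, r.delta_phi, r.p, r.phi_ctrl, r.phi_expt, r.rho))
    out = pd.DataFrame(
        rows, columns=["site", "delta_phi", "p", "phi_ctrl", "phi_expt", "rho"]
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = (out["delta_phi"].abs() >= min_delta) & (out["q"] <= fdr)
    return out
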