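"""Tissue-specific edQTL:eQTL colocalization candidates driven by miRNAs.

The discovery pipeline asks, for each edQTL site: is there at least one
tissue where the editing QTL colocalizes with the gene's expression QTL
(PP4 > 0.75) and at least one tissue where it clearly does not
(PP1 > 0.75)?  Is the site inside an annotated 3'-UTR?  Does some miRNA
target specifically the edited or the unedited transcript at that
position, and is that miRNA expressed more than two-fold higher in the
colocalizing tissues?  Sites passing every gate are candidate events in
which tissue-restricted miRNA degradation converts an edQTL into an eQTL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coloc import ColocResult, coloc_from_assoc
from .mirna import MirnaRecord, editing_specific_target
from .qtl import (
    DEFAULT_MAF_MIN,
    DEFAULT_P_CUTOFF,
    DEFAULT_WINDOW_BP,
    GenotypeTable,
    map_edqtl_all,
    window_assoc_stats,
)
from .quant import SiteCounts, phi_matrix, prefilter_sites

logger = logging.getLogger(__name__)

PP4_MIN = 0.75
PP1_MIN = 0.75
FOLD_CHANGE_MIN = 2.0
_PSEUDOCOUNT = 1e-6


@dataclass
class DiscoveryThresholds:
    """All gate thresholds of the discovery flowchart, with paper defaults."""

    window_bp: int = DEFAULT_WINDOW_BP
    maf_min: float = DEFAULT_MAF_MIN
    p_cutoff: float = DEFAULT_P_CUTOFF
    min_cov: int = 20
    pp4_min: float = PP4_MIN
    pp1_min: float = PP1_MIN
    fold_change_min: float = FOLD_CHANGE_MIN


@dataclass
class CandidateEvent:
    """A (site, miRNA) pair passing every discovery gate."""

    site: object
    gene: str
    lead_snp: object
    coloc_tissues: list[str]
    noncoloc_tissues: list[str]
    mirna: str
    target_version: str
    fold_change: float
    direction_consistent: bool | None = None


def tissue_coloc_classify(
    per_tissue_stats: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    pp4_min: float = PP4_MIN,
    pp1_min: float = PP1_MIN,
    **coloc_kwargs,
):
    """Split tissues into colocalizing / non-colocalizing / ambiguous sets.

    ``per_tissue_stats`` maps tissue -> (edQTL summary stats, eQTL summary
    stats); each tissue is colocalizing when PP4 > pp4_min, non-colocalizing
    when PP1 > pp1_min, else ambiguous.  Tissues without shared SNPs fall
    into the ambiguous set with a warning.
    Returns (coloc set, noncoloc set, ambiguous set, {tissue: ColocResult}).
    """
    coloc_set, noncoloc_set, ambiguous = set(), set(), set()
    results: dict[str, ColocResult] = {}
    for tissue, (ed_stats, e_stats) in per_tissue_stats.items():
        try:
            res = coloc_from_assoc(ed_stats, e_stats, **coloc_kwargs)
        except ValueError as exc:
            logger.warning("tissue %s: %s; marked ambiguous", tissue, exc)
            ambiguous.add(tissue)
            continue
        results[tissue] = res
        if res.pp4 > pp4_min:
            coloc_set.add(tissue)
        elif res.pp1 > pp1_min:
            noncoloc_set.add(tissue)
        else:
            ambiguous.add(tissue)
    return coloc_set, noncoloc_set, ambiguous, results


def utr3_filter(sites: pd.DataFrame, utr_bed: pd.DataFrame) -> list:
    """Sites inside an annotated 3'-UTR on the matching strand.

    Intervals are 0-based half-open; a 1-based site position p overlaps
    when start < p <= end.  Nested or duplicated intervals contribute a
    site once.
    """
    kept = []
    for site, row in sites.iterrows():
        p = int(row["pos"])
        hit = (
            (utr_bed["chrom"] == row["chrom"])
            & (utr_bed["strand"] == row["strand"])
            & (utr_bed["start"] < p)
            & (p <= utr_bed["end"])
        )
        if hit.any():
            kept.append(site)
    return kept


def utr_position(utr_row: pd.Series, site_pos: int) -> int:
    """1-based position of a genomic site within its UTR sequence.

    For + strand UTRs the sequence runs with the genome; for - strand the
    stored sequence is the mRNA 5'->3', i.e. reversed with respect to
    genome coordinates.
    """
    start, end = int(utr_row["start"]), int(utr_row["end"])
    if not (start < site_pos <= end):
        raise ValueError("site outside the UTR interval")
    if utr_row["strand"] == "+":
        return site_pos - start
    return end - site_pos + 1


def mirna_fold_change(
    mirna: MirnaRecord,
    coloc_tissues,
    noncoloc_tissues,
    pseudocount: float = _PSEUDOCOUNT,
) -> float:
    """Mean proxy level over colocalizing tissues / mean over non-colocalizing."""
    if not coloc_tissues or not noncoloc_tissues:
        raise ValueError("both tissue sets must be non-empty")
    num = float(np.mean([mirna.proxy.get(t, 0.0) for t in coloc_tissues]))
    den = float(np.mean([mirna.proxy.get(t, 0.0) for t in noncoloc_tissues]))
    return (num + pseudocount) / (den + pseudocount)


@dataclass
class DiscoveryReport:
    candidates: list[CandidateEvent]
    audit: pd.DataFrame  # site, stage, status, detail
    edqtl: dict  # tissue -> {site -> EdqtlResult}
    coloc: dict  # site -> {tissue -> ColocResult}


def discover_candidates(
    gt: GenotypeTable,
    counts: Mapping[str, SiteCounts],
    expression: Mapping[str, pd.DataFrame],
    utr_bed: pd.DataFrame,
    utr_seqs: Mapping[str, str],
    mirnas: Sequence[MirnaRecord],
    thresholds: DiscoveryThresholds | None = None,
    snp_positions=(),
) -> DiscoveryReport:
    """Run the full discovery flowchart over a multi-tissue cohort.

    Stages, in order: per-tissue site prefilter and edQTL mapping (a site
    proceeds when it is a called edQTL in at least one tissue);
    tissue-by-tissue edQTL:eQTL colocalization with the PP4/PP1 gates;
    3'-UTR membership; editing-specific miRNA seed match at the edited
    position; miRNA fold change > 2 between the colocalizing and
    non-colocalizing tissue sets.  Every input site receives a terminal
    audit entry naming the stage that rejected it (or 'candidate').

    A direction-consistency annotation is attached to candidates: a miRNA
    degrading the unedited pool should give same-sign edQTL and eQTL lead
    slopes, one degrading the edited pool opposite signs.  It annotates
    but never gates.
    """
    th = thresholds or DiscoveryThresholds()
    tissues = list(counts)
    audit_rows: list[tuple] = []

    # Stage 1: per-tissue prefilter + edQTL mapping
    edqtl_by_tissue: dict[str, dict] = {}
    phi_by_tissue: dict[str, pd.DataFrame] = {}
    all_sites = counts[tissues[0]].sites
    for tissue in tissues:
        sc = counts[tissue]
        pre = prefilter_sites(sc, snp_positions)
        phi = phi_matrix(sc, min_cov=th.min_cov)
        phi_by_tissue[tissue] = phi
        kept = pre.kept
        res = map_edqtl_all(
            phi.loc[kept], sc.sites.loc[kept], gt,
            window_bp=th.window_bp, maf_min=th.maf_min, p_cutoff=th.p_cutoff,
        )
        edqtl_by_tissue[tissue] = res

    site_status: dict = {}
    edqtl_sites = []
    for site in all_sites.index:
        hits = [
            t for t in tissues
            if site in edqtl_by_tissue[t] and edqtl_by_tissue[t][site].is_edqtl
        ]
        if hits:
            edqtl_sites.append(site)
        else:
            site_status[site] = ("edqtl", "rejected", "no tissue reaches the edQTL p cutoff")

    # Stage 2: tissue-by-tissue colocalization
    coloc_by_site: dict = {}
    coloc_pass = []
    for site in edqtl_sites:
        gene = all_sites.loc[site, "gene"]
        chrom = all_sites.loc[site, "chrom"]
        pos = int(all_sites.loc[site, "pos"])
        per_tissue_stats = {}
        for tissue in tissues:
            res = edqtl_by_tissue[tissue].get(site)
            if res is None or res.status != "ok":
                continue
            ed_stats = res.assocs.rename(columns={"slope": "beta"})[["snp", "beta", "se"]]
            expr = expression[tissue]
            if gene not in expr.index:
                continue
            y = expr.loc[gene].reindex(gt.samples).to_numpy()
            e_stats = window_assoc_stats(
                y, gt, chrom, pos, th.window_bp, th.maf_min
            )[["snp", "beta", "se"]]
            per_tissue_stats[tissue] = (ed_stats, e_stats)
        cset, nset, _amb, results = tissue_coloc_classify(
            per_tissue_stats, th.pp4_min, th.pp1_min
        )
        coloc_by_site[site] = results
        if cset and nset:
            coloc_pass.append((site, sorted(cset), sorted(nset)))
        else:
            site_status[site] = (
                "coloc", "rejected",
                f"coloc tissues={sorted(cset)} noncoloc={sorted(nset)}",
            )

    # Stage 3: 3'-UTR membership
    utr_pass = []
    in_utr = set(utr3_filter(all_sites, utr_bed))
    for site, cset, nset in coloc_pass:
        if site in in_utr:
            utr_pass.append((site, cset, nset))
        else:
            site_status[site] = ("utr3", "rejected", "site not inside an annotated 3'-UTR")

    # Stages 4-5: editing-specific miRNA + fold change
    candidates: list[CandidateEvent] = []
    for site, cset, nset in utr_pass:
        gene = all_sites.loc[site, "gene"]
        pos = int(all_sites.loc[site, "pos"])
        utr_rows = utr_bed[
            (utr_bed["name"] == gene)
            & (utr_bed["start"] < pos)
            & (pos <= utr_bed["end"])
        ]
        if utr_rows.empty or gene not in utr_seqs:
            site_status[site] = ("mirna", "rejected", "no UTR sequence for the gene")
            continue
        utr_row = utr_rows.iloc[0]
        edit_pos = utr_position(utr_row, pos)
        seq = utr_seqs[gene]
        found_pair = False
        reasons = []
        for m in mirnas:
            try:
                cls = editing_specific_target(seq, edit_pos, m)
            except ValueError as exc:
                reasons.append(f"{m.name}: {exc}")
                continue
            if cls.version not in ("edited", "unedited"):
                reasons.append(f"{m.name}: not editing-specific ({cls.version})")
                continue
            fc = mirna_fold_change(m, cset, nset)
            if fc <= th.fold_change_min:
                reasons.append(f"{m.name}: fold change {fc:.2f} <= {th.fold_change_min}")
                continue
            lead = _best_lead(site, cset, edqtl_by_tissue)
            direction = _direction_consistent(
                site, gene, cset, edqtl_by_tissue, expression, gt,
                all_sites, th, cls.version,
            )
            candidates.append(
                CandidateEvent(
                    site=site,
                    gene=gene,
                    lead_snp=lead,
                    coloc_tissues=list(cset),
                    noncoloc_tissues=list(nset),
                    mirna=m.name,
                    target_version=cls.version,
                    fold_change=float(fc),
                    direction_consistent=direction,
                )
            )
            found_pair = True
        if found_pair:
            site_status[site] = ("done", "candidate", "")
        else:
            site_status[site] = (
                "mirna", "rejected", "; ".join(reasons) or "no miRNA tested"
            )

    for site in all_sites.index:
        stage, status, detail = site_status.get(site, ("done", "candidate", ""))
        audit_rows.append((site, stage, status, detail))
    audit = pd.DataFrame(audit_rows, columns=["site", "stage", "status", "detail"])
    return DiscoveryReport(
        candidates=candidates, audit=audit, edqtl=edqtl_by_tissue, coloc=coloc_by_site
    )


def _best_lead(site, coloc_tissues, edqtl_by_tissue):
    best, best_p = None, np.inf
    for t in coloc_tissues:
        res = edqtl_by_tissue[t].get(site)
        if res is not None and res.lead is not None and res.lead.p < best_p:
            best, best_p = res.lead.snp, res.lead.p
    return best


def _direction_consistent(
    site, gene, coloc_tissues, edqtl_by_tissue, expression, gt, all_sites, th, version
):
    """Same-sign edQTL/eQTL lead slopes for unedited-targeting miRNAs, opposite for edited."""
    from .qtl import ols_assoc

    for t in coloc_tissues:
        res = edqtl_by_tissue[t].get(site)
        if res is None or res.lead is None:
            continue
        expr = expression[t]
        if gene not in expr.index:
            continue
        y = expr.loc[gene].reindex(gt.samples).to_numpy()
        lead_idx = gt.snp_index(res.lead.snp)
        slope_e, _, _, _, _ = ols_assoc(y, gt.dosage[lead_idx])
        if np.isnan(slope_e) or res.lead.slope == 0:
            continue
        same_sign = np.sign(slope_e) == np.sign(res.lead.slope)
        return bool(same_sign) if version == "unedited" else bool(not same_sign)
    return None


def candidates_to_frame(candidates: Sequence[CandidateEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site": c.site,
                "gene": c.gene,
                "lead_snp": c.lead_snp,
                "mirna": c.mirna,
                "target_version": c.target_version,
                "fold_change": c.fold_change,
                "coloc_tissues": ",".join(map(str, c.coloc_tissues)),
                "noncoloc_tissues": ",".join(map(str, c.noncoloc_tissues)),
                "direction_consistent": c.direction_consistent,
            }
            for c in candidates
        ]
    )
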