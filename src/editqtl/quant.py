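"""Editing-level (Phi) quantification and site/sample filters.

The editing level at a site is Phi = G / (A + G), the fraction of reads
carrying the edited base (inosine is read as guanosine by the sequencer).
Sites enter QTL analysis only after coverage, variability and SNP-overlap
filters; individual samples are additionally masked by a per-sample
coverage floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: default per-sample total-coverage floor for QTL analysis
MIN_SAMPLE_COVERAGE = 20

SITE_COLUMNS = ["chrom", "pos", "strand", "gene"]


@dataclass
class SiteCounts:
    """Per-site unedited (A) and edited (G) read counts across samples.

    ``sites`` is indexed by site id with columns chrom, pos (1-based),
    strand and gene; ``a`` and ``g`` are sites x samples integer frames
    sharing that index.  ``allelic`` optionally holds haplotype-resolved
    counts for heterozygous individuals in long form with columns
    site, snp, sample, g_ref, n_ref, g_alt, n_alt.
    """

    sites: pd.DataFrame
    a: pd.DataFrame
    g: pd.DataFrame
    allelic: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.a.index.equals(self.g.index):
            raise ValueError("A and G count frames must share a site index")
        if not self.a.columns.equals(self.g.columns):
            raise ValueError("A and G count frames must share samples")
        if (self.a.to_numpy() < 0).any() or (self.g.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.a.columns)

    @property
    def total(self) -> pd.DataFrame:
        return self.a + self.g


def compute_phi(a, g):
    """Editing level Phi = g / (a + g); NaN where the site has no coverage.

    Accepts scalars or array-likes; negative counts raise.
    """
    a_arr = np.asarray(a, dtype=float)
    g_arr = np.asarray(g, dtype=float)
    if (a_arr < 0).any() or (g_arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = a_arr + g_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(total > 0, g_arr / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(a) and np.isscalar(g):
        return float(phi) if total > 0 else float("nan")
    return phi


def phi_matrix(counts: SiteCounts, min_cov: int = 0) -> pd.DataFrame:
    """Sites x samples Phi frame; entries with total coverage < min_cov are NaN."""
    phi = pd.DataFrame(
        compute_phi(counts.a.to_numpy(), counts.g.to_numpy()),
        index=counts.a.index,
        columns=counts.a.columns,
    )
    if min_cov > 0:
        phi = phi.where(sample_mask(counts, min_cov))
    return phi


def sample_mask(counts: SiteCounts, min_cov: int = MIN_SAMPLE_COVERAGE) -> pd.DataFrame:
    """Boolean frame: True where a sample's total coverage reaches min_cov."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return counts.total >= min_cov


@dataclass
class PrefilterResult:
    kept: list
    reasons: pd.DataFrame  # index site, columns: kept, reason


def prefilter_sites(
    counts: SiteCounts,
    snp_positions: Iterable[tuple[str, int]] | Iterable[int] = (),
    min_mean_edited: float = 2.0,
    min_mean_total: float = 10.0,
    min_quantile_spread: float = 0.10,
) -> PrefilterResult:
    """Site-level filters applied before QTL mapping.

    A site is kept when, across all samples of the tissue: the mean edited
    (G) coverage is >= 2 reads, the mean total (A+G) coverage is >= 10
    reads, the spread between the 90% and 10% quantiles of Phi is at least
    0.10, and the site does not coincide with a known SNP position.

    ``snp_positions`` may contain (chrom, pos) pairs or bare positions
    (then matched on position alone).  Means are taken over every sample,
    including zero-coverage ones; the quantile spread uses type-7
    (linear-interpolation) quantiles over samples with any coverage.
    Returns the kept site ids plus a per-site rejection record listing all
    failed filters.
    """
    snp_set = set(snp_positions)
    a = counts.a.to_numpy(dtype=float)
    g = counts.g.to_numpy(dtype=float)
    total = a + g
    mean_g = g.mean(axis=1)
    mean_total = total.mean(axis=1)
    phi = np.where(total > 0, g / np.where(total > 0, total, 1.0), np.nan)

    kept: list = []
    records = []
    for i, site in enumerate(counts.sites.index):
        fails = []
        if mean_g[i] < min_mean_edited:
            fails.append("mean_edited")
        if mean_total[i] < min_mean_total:
            fails.append("mean_total")
        row = phi[i][~np.isnan(phi[i])]
        if row.size == 0:
            fails.append("quantile_spread")
        else:
            spread = np.quantile(row, 0.9) - np.quantile(row, 0.1)
            if spread < min_quantile_spread:
                fails.append("quantile_spread")
        chrom = counts.sites.loc[site, "chrom"]
        pos = int(counts.sites.loc[site, "pos"])
        if (chrom, pos) in snp_set or pos in snp_set:
            fails.append("snp_overlap")
        if fails:
            records.append((site, False, ";".join(fails)))
        else:
            kept.append(site)
            records.append((site, True, "kept"))
    reasons = pd.DataFrame(
        records, columns=["site", "kept", "reason"]
    ).set_index("site")
    return PrefilterResult(kept=kept, reasons=reasons)
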