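"""SNP quality control and window-based SNP-to-gene assignment.

QC mirrors the usual germline filters: minor allele frequency (MAF) and a
chi-square Hardy-Weinberg equilibrium (HWE) goodness-of-fit test.  Mapping
assigns a SNP to every gene whose +/- flank window (default 5 kb, 1-based
closed coordinates) contains its position; a SNP may map to zero, one or
several genes, and each gene records its mapped-SNP count k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .paired_association import MISSING, PairedGenotypeStudy

log = logging.getLogger(__name__)


@dataclass
class SnpGeneMap:
    """Bidirectional SNP <-> gene window assignment.

    ``gene_to_snps[g]`` lists the distinct SNPs inside gene g's window;
    ``snp_to_genes[s]`` lists every gene whose window holds SNP s;
    ``unmapped_snps`` are SNPs falling in no window (excluded from
    integration).
    """

    gene_to_snps: dict[str, list[str]]
    snp_to_genes: dict[str, list[str]]
    unmapped_snps: list[str] = field(default_factory=list)

    def k(self, gene_id: str) -> int:
        """Number of SNPs mapped to ``gene_id``."""
        return len(self.gene_to_snps[gene_id])

    @property
    def n_incidences(self) -> int:
        """Total number of (SNP, gene) incidence pairs, sum of k over genes."""
        return sum(len(v) for v in self.gene_to_snps.values())

    def restrict_snps(self, snp_ids) -> "SnpGeneMap":
        """Drop SNPs outside ``snp_ids`` (e.g. after QC), pruning empty genes."""
        keep = set(snp_ids)
        g2s = {g: [s for s in snps if s in keep] for g, snps in self.gene_to_snps.items()}
        g2s = {g: snps for g, snps in g2s.items() if snps}
        s2g = {s: genes for s, genes in self.snp_to_genes.items() if s in keep}
        unmapped = [s for s in self.unmapped_snps if s in keep]
        return SnpGeneMap(g2s, s2g, unmapped)


def minor_allele_frequency(genotypes) -> float:
    """Folded allele frequency of a 0/1/2-coded genotype vector.

    Missing calls (``MISSING``) are excluded from the denominator.  The
    result is ``min(f, 1 - f)`` for alternate-allele frequency
    ``f = sum(g) / (2 n)``, hence always in [0, 0.5] and invariant under
    swapping the allele coding (g -> 2 - g).
    """
    g = np.asarray(genotypes)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("all genotype calls missing; SNP unusable")
    f = g.sum() / (2.0 * g.size)
    return float(min(f, 1.0 - f))


def hwe_test(genotype_counts) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit p-value.

    ``genotype_counts`` is the (n_AA, n_AB, n_BB) tally.  The allele
    frequency is estimated from the same counts; a monomorphic SNP has no
    testable departure and returns p = 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("empty genotype counts")
    f = (n_ab + 2 * n_bb) / (2.0 * n)
    if f == 0.0 or f == 1.0:
        return 1.0
    expected = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(g: np.ndarray) -> tuple[int, int, int]:
    g = g[g != MISSING]
    return (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))


def filter_snps(
    study: PairedGenotypeStudy,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.05,
    hwe_condition: str = "a",
) -> tuple[list[str], pd.DataFrame]:
    """Apply MAF and HWE filters; return retained SNPs and a decision log.

    Removal is strict: MAF below ``maf_min`` or HWE p below ``hwe_alpha``
    drops the SNP, boundary values are retained.  MAF and HWE are computed
    on condition A (normal tissue) by default -- tumor genotypes may break
    HWE for somatic rather than technical reasons -- pass
    ``hwe_condition="both"`` to pool all calls instead.  A SNP failing both
    filters is logged under the MAF rule (first-failing-rule convention).
    """
    if not (0 < maf_min < 1) or not (0 < hwe_alpha < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if hwe_condition not in ("a", "both"):
        raise ValueError("hwe_condition must be 'a' or 'both'")
    if study.n_snps == 0:
        log.warning("filter_snps called on an empty study")
        return [], pd.DataFrame(columns=["snp_id", "maf", "hwe_p", "decision"])

    retained, rows = [], []
    for j, snp in enumerate(study.snp_ids):
        if hwe_condition == "a":
            calls = study.condition_a[:, j]
        else:
            calls = np.concatenate([study.condition_a[:, j], study.condition_b[:, j]])
        try:
            maf = minor_allele_frequency(calls)
        except ValueError:
            rows.append((snp, np.nan, np.nan, "removed_all_missing"))
            continue
        hwe_p = hwe_test(_genotype_counts(calls))
        if maf < maf_min:
            decision = "removed_maf"
        elif hwe_p < hwe_alpha:
            decision = "removed_hwe"
        else:
            decision = "retained"
            retained.append(snp)
        rows.append((snp, maf, hwe_p, decision))
    decisions = pd.DataFrame(rows, columns=["snp_id", "maf", "hwe_p", "decision"])
    log.info(
        "SNP QC: %d in, %d retained, %d failed MAF, %d failed HWE",
        study.n_snps, len(retained),
        int((decisions["decision"] == "removed_maf").sum()),
        int((decisions["decision"] == "removed_hwe").sum()),
    )
    return retained, decisions


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 5000,
) -> SnpGeneMap:
    """Assign SNPs to genes whose flanked window contains them.

    ``snps`` needs columns (snp_id, chrom, pos); ``genes`` needs
    (gene_id, chrom, start, end) with 1-based closed intervals.  SNP s maps
    to gene g iff the chromosomes match and
    ``start - flank <= pos <= end + flank`` (both ends inclusive).  The
    window is symmetric, so strand never changes the assignment.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene annotation with start > end")

    snp_to_genes: dict[str, list[str]] = {s: [] for s in snps["snp_id"]}
    gene_to_snps: dict[str, list[str]] = {}
    for chrom, gene_grp in genes.groupby("chrom", sort=False):
        snp_grp = snps[snps["chrom"] == chrom]
        if snp_grp.empty:
            for g in gene_grp["gene_id"]:
                gene_to_snps[g] = []
            continue
        order = np.argsort(snp_grp["pos"].to_numpy(), kind="stable")
        pos = snp_grp["pos"].to_numpy()[order]
        ids = snp_grp["snp_id"].to_numpy()[order]
        lo = np.searchsorted(pos, gene_grp["start"].to_numpy() - flank, side="left")
        hi = np.searchsorted(pos, gene_grp["end"].to_numpy() + flank, side="right")
        for g, a, b in zip(gene_grp["gene_id"], lo, hi):
            hits = list(ids[a:b])
            gene_to_snps[g] = hits
            for s in hits:
                snp_to_genes[s].append(g)
    # genes on chromosomes absent from the SNP table
    for g in genes["gene_id"]:
        gene_to_snps.setdefault(g, [])
    unmapped = [s for s, gl in snp_to_genes.items() if not gl]
    if unmapped:
        log.info("%d of %d SNPs map to no gene window", len(unmapped), len(snp_to_genes))
    return SnpGeneMap(gene_to_snps, snp_to_genes, unmapped)
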