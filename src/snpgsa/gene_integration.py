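"""SNP-to-gene p-value integration and LD dependency correction.

A gene with k mapped SNPs gets one representative p-value by one of three
combiners:

* minimum   -- ``p_gene = min_i p_i`` (the common GWAS practice);
* fisher    -- ``F = -2 * sum(ln p_i)`` referred to chi-square with 2k df;
* stouffer  -- ``Z_i = Phi^-1(p_i)``, ``Z_gene = sum(Z_i) / sqrt(k)``
  referred to the standard normal lower tail, so small inputs give small
  outputs and k = 1 is an exact identity.

Within-gene SNPs are correlated through linkage disequilibrium, so the
combined p-value is optionally deflated with a Dunn-Sidak-style correction
whose exponent assumes roughly half of the SNPs are effectively
independent::

    p_corr = 1 - (1 - p_gene) ** ((k + 1) / 2)

which is the identity at k = 1 and satisfies p_corr >= p_gene for k >= 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .variant_qc import SnpGeneMap

log = logging.getLogger(__name__)

METHODS = ("minimum", "fisher", "stouffer")

# clamp bounds applied before log / normal-quantile transforms; wide enough
# to never move a result at realistic precision
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


def _as_pvalues(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def combine_minimum(p_values) -> float:
    """Smallest of the k SNP p-values."""
    return float(_as_pvalues(p_values).min())


def combine_fisher(p_values) -> tuple[float, float]:
    """Fisher probability integration: ``F = -2 sum(ln p)`` vs chi2(2k)."""
    p = np.clip(_as_pvalues(p_values), _P_FLOOR, 1.0)
    f = float(-2.0 * np.log(p).sum())
    return f, float(stats.chi2.sf(f, df=2 * p.size))


def combine_stouffer(p_values) -> tuple[float, float]:
    """Stouffer (z-transformation) integration, lower-tail convention."""
    p = np.clip(_as_pvalues(p_values), _P_FLOOR, _P_CEIL)
    z = float(ndtri(p).sum() / np.sqrt(p.size))
    return z, float(ndtr(z))


def ld_correct(p_gene: float, k: int) -> float:
    """LD-aware Dunn-Sidak correction ``1 - (1 - p)^((k+1)/2)``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < p_gene <= 1:
        raise ValueError("p_gene must lie in (0, 1]")
    return float(1.0 - (1.0 - p_gene) ** ((k + 1) / 2.0))


# -- vectorized grouped combiners ------------------------------------------
#
# The permutation loops of i-GSEA4GWAS re-integrate thousands of times, so
# the per-gene combiners also exist in a grouped form driven by reduceat.

class GeneGroups:
    """Flat index of SNP positions grouped by gene, for fast re-integration.

    ``index`` concatenates, gene by gene, the positions of each gene's SNPs
    within a fixed SNP-id order; ``starts`` marks group boundaries and
    ``ks`` the group sizes.
    """

    def __init__(self, snp_gene_map: SnpGeneMap, snp_ids: list[str]):
        pos = {s: i for i, s in enumerate(snp_ids)}
        genes, chunks = [], []
        for g, snps in snp_gene_map.gene_to_snps.items():
            found = [pos[s] for s in snps if s in pos]
            if found:
                genes.append(g)
                chunks.append(np.asarray(found, dtype=np.intp))
            elif snps:
                log.warning("gene %s has no association results; omitted", g)
        self.gene_ids = np.asarray(genes, dtype=object)
        self.ks = np.asarray([c.size for c in chunks], dtype=np.intp)
        self.index = (
            np.concatenate(chunks) if chunks else np.empty(0, dtype=np.intp)
        )
        self.starts = np.concatenate([[0], np.cumsum(self.ks)[:-1]]).astype(np.intp)

    def combine(self, snp_p: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (statistic, combined p) arrays, one entry per gene."""
        if method not in METHODS:
            raise ValueError(f"unknown integration method {method!r}; choose from {METHODS}")
        if self.index.size == 0:
            return np.empty(0), np.empty(0)
        vals = np.asarray(snp_p, dtype=float)[self.index]
        if method == "minimum":
            p = np.minimum.reduceat(vals, self.starts)
            return p.copy(), p
        if method == "fisher":
            f = -2.0 * np.add.reduceat(np.log(np.clip(vals, _P_FLOOR, 1.0)), self.starts)
            return f, stats.chi2.sf(f, df=2 * self.ks)
        z = np.add.reduceat(
            ndtri(np.clip(vals, _P_FLOOR, _P_CEIL)), self.starts
        ) / np.sqrt(self.ks)
        return z, ndtr(z)

    def ld_correct(self, p_gene: np.ndarray) -> np.ndarray:
        return 1.0 - (1.0 - p_gene) ** ((self.ks + 1) / 2.0)


def integrate_genes(
    associations: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    method: str = "stouffer",
    apply_ld: bool = True,
) -> pd.DataFrame:
    """Collapse per-SNP p-values into per-gene scores.

    ``associations`` is the output of
    :func:`snpgsa.paired_association.associate_all`; SNPs with a flagged
    error (NaN p-value) are ignored.  Returns a DataFrame with columns
    ``gene_id, method, k, statistic, p_gene, ld_corrected, p_corr``; when
    ``apply_ld`` is off, ``p_corr`` simply repeats ``p_gene``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown integration method {method!r}; choose from {METHODS}")
    ok = associations[associations["p_value"].notna()]
    snp_ids = ok["snp_id"].tolist()
    groups = GeneGroups(snp_gene_map, snp_ids)
    stat, p_gene = groups.combine(ok["p_value"].to_numpy(), method)
    p_corr = groups.ld_correct(p_gene) if apply_ld else p_gene.copy()
    return pd.DataFrame(
        {
            "gene_id": groups.gene_ids,
            "method": method,
            "k": groups.ks,
            "statistic": stat,
            "p_gene": p_gene,
            "ld_corrected": bool(apply_ld),
            "p_corr": p_corr,
        }
    )


def effective_pvalues(gene_scores: pd.DataFrame) -> np.ndarray:
    """Per-gene p-values as downstream algorithms should see them.

    Uses the LD-corrected column when the scores were integrated with the
    correction enabled, otherwise the raw combined p-value.
    """
    if len(gene_scores) and bool(gene_scores["ld_corrected"].iloc[0]):
        return gene_scores["p_corr"].to_numpy(dtype=float)
    return gene_scores["p_gene"].to_numpy(dtype=float)
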