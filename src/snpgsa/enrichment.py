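"""Six gene set analysis algorithms for SNP-level GWAS results.

All algorithms test the competitive null (the set is no more associated
than the genes outside it) against a collection of named gene sets:

* ``gsea``        -- weighted Kolmogorov-Smirnov running-sum enrichment
  score (ES) on genes ranked by ``-log10(p_gene)``, gene-label permutation
  null, size-normalized NES;
* ``gsea_snp``    -- same running-sum machinery with SNPs as the ranked
  units (no integration step), SNP-label permutation null;
* ``igsea4gwas``  -- ES rescaled by the set's vs universe's proportion of
  "significant" genes (genes carrying at least one of the top 5% SNPs),
  SNP-label permutation with per-round re-integration;
* ``magenta75``   -- leading-edge fraction: set members with p below the
  75th percentile of all gene p-values, mock-set permutation null;
* ``ora``         -- hypergeometric over-representation of genes below a
  significance threshold;
* ``cerno``       -- analytic Fisher combination of ``rank / N`` values,
  chi-square with 2|S| degrees of freedom.

Permutation p-values use the add-one convention and, for the signed ES
statistics, the two-null-distribution rule: an observed score is compared
only against permuted scores of the same sign.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_integration import METHODS, GeneGroups, effective_pvalues, integrate_genes
from .variant_qc import SnpGeneMap

log = logging.getLogger(__name__)

ALGORITHMS = ("gsea", "gsea_snp", "igsea4gwas", "magenta75", "ora", "cerno")


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional target (ground-truth) flag."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        # deduplicate members while preserving order
        self.sets = {name: list(dict.fromkeys(m)) for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def description(self, name: str) -> str:
        return self.descriptions.get(name, "")


@dataclass
class RankedList:
    """Items sorted by rank metric ``r = -log10(p)``, descending.

    Ties are broken by identifier (lexical, ascending) so permutation
    runs are reproducible regardless of input order.
    """

    ids: np.ndarray
    r: np.ndarray

    @property
    def n(self) -> int:
        return self.ids.size


def _ranked_order(ids: np.ndarray, r: np.ndarray) -> np.ndarray:
    id_rank = np.argsort(np.argsort(ids.astype(str), kind="stable"))
    return np.lexsort((id_rank, -r))


def make_ranked_list(ids, p_values) -> RankedList:
    """Rank items by ``-log10(p)``, largest (most significant) first."""
    ids = np.asarray(ids, dtype=object)
    p = np.asarray(p_values, dtype=float)
    r = -np.log10(np.clip(p, 1e-300, 1.0))
    order = _ranked_order(ids, r)
    return RankedList(ids[order], r[order])


def rank_genes(gene_scores: pd.DataFrame) -> RankedList:
    """Ranked gene list from integrated scores (LD-corrected if enabled)."""
    return make_ranked_list(gene_scores["gene_id"].to_numpy(), effective_pvalues(gene_scores))


def _membership(
    sets: GeneSetCollection,
    universe: np.ndarray,
    min_set_size: int,
    max_is_proper: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Boolean membership matrix (sets x universe) after size filtering."""
    pos = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    names, rows = [], []
    for name, members in sets.sets.items():
        idx = [pos[m] for m in members if m in pos]
        size = len(idx)
        if size < min_set_size:
            log.info("set %s dropped: %d members in universe < %d", name, size, min_set_size)
            continue
        if max_is_proper and size >= n:
            log.info("set %s dropped: spans the whole universe", name)
            continue
        row = np.zeros(n, dtype=bool)
        row[idx] = True
        names.append(name)
        rows.append(row)
    H = np.asarray(rows, dtype=bool) if rows else np.zeros((0, n), dtype=bool)
    return names, H


def _es_for_sets(r: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enrichment scores for every row of membership matrix ``H``.

    ``r`` is the rank metric in ranked order (non-negative).  Rows whose
    members all carry zero rank weight have no defined hit profile and get
    ES = 0.  Returns (ES, extremum position) arrays.
    """
    n = r.size
    nh = H.sum(axis=1)
    if np.any(nh >= n) or np.any(nh < 1):
        raise ValueError("each set must satisfy 1 <= |S| < N for the running sum")
    w = np.abs(r)
    nr = H @ w
    p_hit = np.cumsum(H * w, axis=1)
    np.divide(p_hit, nr[:, None], out=p_hit, where=nr[:, None] > 0)
    p_miss = np.cumsum(~H, axis=1) / (n - nh)[:, None]
    dev = p_hit - p_miss
    absdev = np.abs(dev)
    # first position attaining the maximum deviation, up to float noise
    pos = np.argmax(absdev >= absdev.max(axis=1, keepdims=True) - 1e-12, axis=1)
    es = np.take_along_axis(dev, pos[:, None], axis=1).ravel()
    es[nr == 0] = 0.0
    return es, pos


def running_enrichment_score(
    ranked: RankedList, gene_set
) -> tuple[float, int, np.ndarray, np.ndarray]:
    """ES of one set: running hit/miss profiles and their extreme deviation.

    ``P_hit`` accumulates the set members' |r| weights normalized by their
    total ``N_R``; ``P_miss`` accumulates ``1 / (N - N_H)`` for non-members.
    The ES is the signed deviation ``P_hit - P_miss`` at the position of
    maximum absolute deviation (first such position on ties).  Raises if no
    set member carries positive rank weight (degenerate set).
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.ids), dtype=bool, count=ranked.n)
    nh = int(hit.sum())
    if not 1 <= nh < ranked.n:
        raise ValueError("set must contain between 1 and N-1 ranked items")
    w = np.abs(ranked.r)
    nr = (w * hit).sum()
    if nr == 0:
        raise ValueError("degenerate set: all member ranks are zero")
    p_hit = np.cumsum(w * hit) / nr
    p_miss = np.cumsum(~hit) / (ranked.n - nh)
    dev = p_hit - p_miss
    absdev = np.abs(dev)
    pos = int(np.argmax(absdev >= absdev.max() - 1e-12))
    return float(dev[pos]), pos, p_hit, p_miss


def _same_sign_stats(
    es: np.ndarray, es_perm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-null-distribution normalization and p-values for signed scores.

    Per set: permuted scores sharing the observed sign form the null; NES
    is the observed score over the mean magnitude of that null, and the
    p-value counts null magnitudes at or above the observed one (add-one
    rule).  A zero observed score, or an empty same-sign null, yields
    p = 1 and NaN NES.
    """
    n_sets = es.size
    nes = np.full(n_sets, np.nan)
    pvals = np.ones(n_sets)
    for s in range(n_sets):
        e = es[s]
        if e == 0:
            continue
        same = es_perm[:, s][np.sign(es_perm[:, s]) == np.sign(e)]
        if same.size == 0:
            log.warning("set %d: no same-sign permutations; p set to 1", s)
            continue
        nes[s] = e / np.abs(same).mean()
        pvals[s] = (np.count_nonzero(np.abs(same) >= abs(e)) + 1) / (same.size + 1)
    return nes, pvals


def _result_frame(
    algorithm: str,
    set_ids: list[str],
    statistic: np.ndarray,
    p: np.ndarray,
    set_size: np.ndarray,
    n_hits: np.ndarray,
) -> pd.DataFrame:
    p = np.asarray(p, dtype=float)
    p_adj = multipletests(p, method="fdr_bh")[1] if p.size else np.empty(0)
    return pd.DataFrame(
        {
            "algorithm": algorithm,
            "set_id": set_ids,
            "statistic": np.asarray(statistic, dtype=float),
            "p": p,
            "p_adj": p_adj,
            "set_size": np.asarray(set_size, dtype=int),
            "n_hits": np.asarray(n_hits, dtype=int),
        }
    )


def _combo_rng(seed: int, tag: str) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    return np.random.default_rng(ss)


# -- GSEA and GSEA-SNP ------------------------------------------------------

def _gsea_core(
    algorithm: str,
    ranked: RankedList,
    sets: GeneSetCollection,
    snp_membership: dict[str, list[str]] | None,
    n_perm: int,
    rng: np.random.Generator,
    min_set_size: int,
) -> pd.DataFrame:
    if snp_membership is None:
        collection = sets
    else:
        # a SNP belongs to a set iff it maps to any member gene
        collection = GeneSetCollection(
            {
                name: [s for s, genes in snp_membership.items()
                       if any(g in members for g in genes)]
                for name, members in ((nm, set(m)) for nm, m in sets.sets.items())
            }
        )
    names, H = _membership(collection, ranked.ids, min_set_size, max_is_proper=True)
    if not names:
        return _result_frame(algorithm, [], [], [], [], [])
    es, pos = _es_for_sets(ranked.r, H)
    es_perm = np.empty((n_perm, len(names)))
    for b in range(n_perm):
        perm = rng.permutation(ranked.n)
        es_perm[b], _ = _es_for_sets(ranked.r, H[:, perm])
    nes, pvals = _same_sign_stats(es, es_perm)
    leading = np.array([int(H[s, : pos[s] + 1].sum()) for s in range(len(names))])
    return _result_frame(algorithm, names, nes, pvals, H.sum(axis=1), leading)


def gsea(
    gene_scores: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """GSEA on integrated gene scores with gene-label permutation.

    The reported statistic is the NES: the observed ES divided by the mean
    magnitude of same-direction permuted scores.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _gsea_core("gsea", rank_genes(gene_scores), sets, None, n_perm, rng, min_set_size)


def gsea_snp(
    associations: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """GSEA-SNP: the running sum walks the ranked SNPs, no integration.

    A SNP counts as a set member when it maps into any of the set's genes;
    the null permutes SNP labels.
    """
    ok = associations[associations["p_value"].notna()]
    ranked = make_ranked_list(ok["snp_id"].to_numpy(), ok["p_value"].to_numpy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _gsea_core(
        "gsea_snp", ranked, sets, snp_gene_map.snp_to_genes, n_perm, rng, min_set_size
    )


# -- i-GSEA4GWAS ------------------------------------------------------------

def igsea4gwas(
    associations: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    sets: GeneSetCollection,
    method: str = "minimum",
    apply_ld: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    top_snp_fraction: float = 0.05,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """i-GSEA4GWAS: significance-proportion-rescaled enrichment score.

    A gene is "significant" when at least one of its SNPs lies among the
    top ``top_snp_fraction`` of all SNPs by association p-value.  The ES
    of each set is multiplied by k/K -- the significant-gene proportion
    inside the set over the proportion in the whole universe -- giving the
    SPES.  The null permutes SNP labels and repeats integration, ranking
    and scoring in every round.
    """
    if not 0 < top_snp_fraction < 1:
        raise ValueError("top_snp_fraction must lie in (0, 1)")
    ok = associations[associations["p_value"].notna()]
    snp_p = ok["p_value"].to_numpy(dtype=float)
    groups = GeneGroups(snp_gene_map, ok["snp_id"].tolist())
    if groups.gene_ids.size == 0:
        return _result_frame("igsea4gwas", [], [], [], [], [])
    m_top = max(1, math.ceil(top_snp_fraction * snp_p.size))
    names, H0 = _membership(sets, groups.gene_ids, min_set_size, max_is_proper=True)
    if not names:
        return _result_frame("igsea4gwas", [], [], [], [], [])
    id_rank = np.argsort(np.argsort(groups.gene_ids.astype(str), kind="stable"))

    def score(p_snp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        _, p_gene = groups.combine(p_snp, method)
        if apply_ld:
            p_gene = groups.ld_correct(p_gene)
        r = -np.log10(np.clip(p_gene, 1e-300, 1.0))
        order = np.lexsort((id_rank, -r))
        es, pos = _es_for_sets(r[order], H0[:, order])
        thr = np.partition(p_snp, m_top - 1)[m_top - 1]
        gene_min = np.minimum.reduceat(p_snp[groups.index], groups.starts)
        sig = gene_min <= thr
        return es, sig, pos

    es, sig, pos = score(snp_p)
    big_k = sig.mean()
    if big_k == 0:
        raise ValueError("no significant genes in the universe; provide more SNPs")
    nh = H0.sum(axis=1)
    small_k = (H0 @ sig.astype(np.float64)) / nh
    spes = es * (small_k / big_k)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spes_perm = np.empty((n_perm, len(names)))
    for b in range(n_perm):
        p_b = rng.permutation(snp_p)
        es_b, sig_b, _ = score(p_b)
        kb = sig_b.mean()
        ratio = ((H0 @ sig_b.astype(np.float64)) / nh) / kb if kb > 0 else np.zeros(len(names))
        spes_perm[b] = es_b * ratio
    _, pvals = _same_sign_stats(spes, spes_perm)
    # leading-edge size at the observed extremum position
    _, p_gene_obs = groups.combine(snp_p, method)
    if apply_ld:
        p_gene_obs = groups.ld_correct(p_gene_obs)
    r_obs = -np.log10(np.clip(p_gene_obs, 1e-300, 1.0))
    order = np.lexsort((id_rank, -r_obs))
    H_ord = H0[:, order]
    leading = np.array([int(H_ord[s, : pos[s] + 1].sum()) for s in range(len(names))])
    return _result_frame("igsea4gwas", names, spes, pvals, nh, leading)


# -- MAGENTA75 ---------------------------------------------------------------

def magenta75(
    gene_scores: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    percentile: float = 75.0,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """MAGENTA leading-edge-fraction test at a global percentile cutoff.

    The cutoff is the given percentile of all gene p-values; the observed
    statistic counts set members strictly below it.  The null draws mock
    sets of identical size uniformly without replacement from the
    universe, which makes each mock count a hypergeometric draw -- sampled
    as such for speed.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    p = effective_pvalues(gene_scores)
    universe = gene_scores["gene_id"].to_numpy(dtype=object)
    names, H = _membership(sets, universe, min_set_size)
    if not names:
        return _result_frame("magenta75", [], [], [], [], [])
    cutoff = np.percentile(p, percentile)
    sig = p < cutoff
    n, s_total = p.size, int(sig.sum())
    nh = H.sum(axis=1)
    if np.any(nh > n):
        raise ValueError("set larger than the universe")
    obs = H @ sig.astype(np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pvals = np.empty(len(names))
    for s in range(len(names)):
        mock = rng.hypergeometric(s_total, n - s_total, nh[s], size=n_perm)
        pvals[s] = (np.count_nonzero(mock >= obs[s]) + 1) / (n_perm + 1)
    return _result_frame("magenta75", names, obs.astype(float), pvals, nh, obs)


# -- ORA ---------------------------------------------------------------------

def ora(
    gene_scores: pd.DataFrame,
    sets: GeneSetCollection,
    deg_alpha: float = 0.05,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of significant genes.

    Genes with (LD-corrected, when enabled) p below ``deg_alpha`` form the
    significant list; each set's p-value is the upper-tail hypergeometric
    probability of its overlap with that list.  The statistic column holds
    the odds ratio of the 2x2 table.
    """
    if not 0 < deg_alpha < 1:
        raise ValueError("deg_alpha must lie in (0, 1)")
    p = effective_pvalues(gene_scores)
    universe = gene_scores["gene_id"].to_numpy(dtype=object)
    names, H = _membership(sets, universe, min_set_size)
    if not names:
        return _result_frame("ora", [], [], [], [], [])
    deg = p < deg_alpha
    n, d = p.size, int(deg.sum())
    nh = H.sum(axis=1)
    x = H @ deg.astype(np.int64)
    if d == 0:
        log.warning("ORA: no gene passes the %.3g significance cut; all p = 1", deg_alpha)
        pvals = np.ones(len(names))
    else:
        pvals = stats.hypergeom.sf(x - 1, n, d, nh)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (x * (n - nh - d + x)) / ((nh - x) * (d - x))
    return _result_frame("ora", names, odds, pvals, nh, x)


# -- CERNO -------------------------------------------------------------------

def cerno(
    gene_scores: pd.DataFrame,
    sets: GeneSetCollection,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """CERNO: analytic Fisher combination of relative ranks.

    Genes are ranked 1..N ascending by p-value (rank 1 = most significant,
    average ranks on ties); the statistic ``F = -2 sum(ln(rank / N))``
    over the set members is referred to chi-square with 2|S| degrees of
    freedom.  No permutations are involved.
    """
    p = effective_pvalues(gene_scores)
    if p.size < 2:
        raise ValueError("CERNO needs a universe of at least 2 genes")
    universe = gene_scores["gene_id"].to_numpy(dtype=object)
    names, H = _membership(sets, universe, min_set_size)
    if not names:
        return _result_frame("cerno", [], [], [], [], [])
    ranks = stats.rankdata(p, method="average")
    lnr = np.log(ranks / p.size)
    f = -2.0 * (H @ lnr)
    nh = H.sum(axis=1)
    pvals = stats.chi2.sf(f, df=2 * nh)
    return _result_frame("cerno", names, f, pvals, nh, nh)


# -- pipeline over all combinations -----------------------------------------

def run_all(
    associations: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    sets: GeneSetCollection,
    algorithms=ALGORITHMS,
    integrations=METHODS,
    ld_options=(False, True),
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = 5,
    deg_alpha: float = 0.05,
    percentile: float = 75.0,
    top_snp_fraction: float = 0.05,
) -> pd.DataFrame:
    """Run every requested algorithm x integration x LD combination.

    Returns one tidy long-format table with provenance columns
    ``(algorithm, integration, ld)``.  GSEA-SNP skips the integration step
    by construction, so it contributes a single combination tagged
    ``integration='none', ld=False``.  Sub-seeds are derived from the
    master seed and the combination tag, so results do not depend on the
    iteration order.
    """
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(f"unknown algorithm(s) {unknown}; valid names: {list(ALGORITHMS)}")
    frames = []
    score_cache: dict[tuple[str, bool], pd.DataFrame] = {}

    def scores_for(method: str, ld: bool) -> pd.DataFrame:
        if (method, ld) not in score_cache:
            score_cache[(method, ld)] = integrate_genes(
                associations, snp_gene_map, method=method, apply_ld=ld
            )
        return score_cache[(method, ld)]

    for alg in algorithms:
        if alg == "gsea_snp":
            res = gsea_snp(
                associations, snp_gene_map, sets,
                n_perm=n_perm, seed=_combo_rng(seed, "gsea_snp"),
                min_set_size=min_set_size,
            )
            res["integration"] = "none"
            res["ld"] = False
            frames.append(res)
            continue
        for method in integrations:
            for ld in ld_options:
                tag = f"{alg}:{method}:{int(ld)}"
                if alg == "gsea":
                    res = gsea(scores_for(method, ld), sets, n_perm=n_perm,
                               seed=_combo_rng(seed, tag), min_set_size=min_set_size)
                elif alg == "igsea4gwas":
                    res = igsea4gwas(
                        associations, snp_gene_map, sets, method=method, apply_ld=ld,
                        n_perm=n_perm, seed=_combo_rng(seed, tag),
                        top_snp_fraction=top_snp_fraction, min_set_size=min_set_size,
                    )
                elif alg == "magenta75":
                    res = magenta75(scores_for(method, ld), sets, n_perm=n_perm,
                                    seed=_combo_rng(seed, tag), percentile=percentile,
                                    min_set_size=min_set_size)
                elif alg == "ora":
                    res = ora(scores_for(method, ld), sets, deg_alpha=deg_alpha,
                              min_set_size=min_set_size)
                else:
                    res = cerno(scores_for(method, ld), sets, min_set_size=min_set_size)
                res["integration"] = method
                res["ld"] = bool(ld)
                frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    n_combos = out.groupby(["algorithm", "integration", "ld"]).ngroups
    log.info("run_all: %d combinations, %d result rows", n_combos, len(out))
    cols = ["algorithm", "integration", "ld", "set_id", "statistic", "p", "p_adj",
            "set_size", "n_hits"]
    return out[cols]
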