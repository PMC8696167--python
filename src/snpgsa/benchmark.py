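"""Four-metric evaluation of enrichment pipelines.

A *pipeline* is any callable ``(study, seed) -> DataFrame`` whose output
has one row per gene set with at least ``set_id`` and ``p`` columns;
:class:`GsaPipeline` wires QC, paired association, integration and one
enrichment algorithm into such a callable.  The metrics:

sensitivity
    Proportion of truly alternative hypotheses among the collection's
    p-values, ``1 - pi0`` with pi0 from Storey's smoother estimator.
prioritization
    Median rank of the target sets when all sets are ordered by p-value
    (rank 1 = most significant; lower is better).
specificity
    Deviation of the mean false-positive rate from the nominal 5% over
    phenotype permutations (per-subject condition swaps, preserving the
    paired design).
reproducibility
    AUC of the fraction of commonly detected sets across disjoint subject
    subsets, over a grid of top-c cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import enrichment as enr
from .enrichment import GeneSetCollection
from .gene_integration import integrate_genes
from .paired_association import PairedGenotypeStudy, associate_all
from .variant_qc import SnpGeneMap, filter_snps, map_snps_to_genes

log = logging.getLogger(__name__)


@dataclass
class GsaPipeline:
    """Full analysis chain for one algorithm x integration x LD choice.

    Calling the instance (or :meth:`run`) executes SNP QC, the paired
    association test, SNP-to-gene integration (unless the algorithm is
    SNP-level) and the enrichment algorithm, returning the enrichment
    result table.
    """

    snps: pd.DataFrame
    genes: pd.DataFrame
    sets: GeneSetCollection
    algorithm: str = "cerno"
    integration: str = "stouffer"
    apply_ld: bool = True
    maf_min: float = 0.05
    hwe_alpha: float = 0.05
    flank: int = 5000
    n_perm_assoc: int = 999
    n_perm_enrich: int = 199
    min_set_size: int = 5
    deg_alpha: float = 0.05
    percentile: float = 75.0
    top_snp_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.algorithm not in enr.ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid names: {list(enr.ALGORITHMS)}"
            )
        self._full_map: SnpGeneMap = map_snps_to_genes(self.snps, self.genes, self.flank)

    def run(self, study: PairedGenotypeStudy, seed: int = 0) -> pd.DataFrame:
        retained, _ = filter_snps(study, self.maf_min, self.hwe_alpha)
        mapped = self._full_map.restrict_snps(retained)
        usable = sorted(mapped.snp_to_genes.keys())
        assoc = associate_all(study, usable, n_perm=self.n_perm_assoc, seed=seed)
        if self.algorithm == "gsea_snp":
            return enr.gsea_snp(assoc, mapped, self.sets, n_perm=self.n_perm_enrich,
                                seed=seed, min_set_size=self.min_set_size)
        if self.algorithm == "igsea4gwas":
            return enr.igsea4gwas(
                assoc, mapped, self.sets, method=self.integration,
                apply_ld=self.apply_ld, n_perm=self.n_perm_enrich, seed=seed,
                top_snp_fraction=self.top_snp_fraction, min_set_size=self.min_set_size,
            )
        scores = integrate_genes(assoc, mapped, self.integration, self.apply_ld)
        if self.algorithm == "gsea":
            return enr.gsea(scores, self.sets, n_perm=self.n_perm_enrich,
                            seed=seed, min_set_size=self.min_set_size)
        if self.algorithm == "magenta75":
            return enr.magenta75(scores, self.sets, n_perm=self.n_perm_enrich,
                                 seed=seed, percentile=self.percentile,
                                 min_set_size=self.min_set_size)
        if self.algorithm == "ora":
            return enr.ora(scores, self.sets, deg_alpha=self.deg_alpha,
                           min_set_size=self.min_set_size)
        return enr.cerno(scores, self.sets, min_set_size=self.min_set_size)

    __call__ = run


# -- metric 1: sensitivity ---------------------------------------------------

def sensitivity_storey(p_values, lambdas=None) -> float:
    """``1 - pi0`` with pi0 from Storey's smoother estimator.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is evaluated on a
    lambda grid (default 0.05..0.95, step 0.05), smoothed with a cubic
    polynomial and read off at the largest lambda, then clipped to [0, 1].
    With fewer than 20 p-values the single-lambda (0.5) estimate is used
    instead, with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1] and be non-empty")
    if p.size < 20:
        log.warning("only %d p-values; falling back to single-lambda pi0", p.size)
        pi0 = np.count_nonzero(p > 0.5) / (p.size * 0.5)
        return float(1.0 - np.clip(pi0, 0.0, 1.0))
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_grid = np.array([np.count_nonzero(p > lam) / (p.size * (1 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_grid, deg=3)
    pi0 = float(np.clip(np.polyval(coef, lambdas.max()), 0.0, 1.0))
    return 1.0 - pi0


# -- metric 2: prioritization ------------------------------------------------

def prioritization(results: pd.DataFrame, targets) -> float:
    """Median rank of the target sets (rank 1 = smallest p, average ties)."""
    targets = set(targets)
    hit = results["set_id"].isin(targets)
    if not hit.any():
        raise ValueError("none of the target sets appear in the results")
    ranks = stats.rankdata(results["p"].to_numpy(), method="average")
    return float(np.median(ranks[hit.to_numpy()]))


# -- metric 3: specificity ---------------------------------------------------

def specificity_fpr(
    pipeline,
    study: PairedGenotypeStudy,
    n_label_perms: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean FPR over phenotype permutations and its deviation from alpha.

    Each permutation swaps the two condition labels within every subject
    independently with probability 1/2 (the only relabelling consistent
    with the paired design) and reruns the full pipeline.  A failing
    permutation is logged and skipped.  Returns ``(mean_fpr,
    |mean_fpr - alpha|)``.
    """
    rng = np.random.default_rng(seed)
    fprs = []
    failures = 0
    for i in range(n_label_perms):
        mask = rng.random(study.n_pairs) < 0.5
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = pipeline(study.swap_conditions(mask), sub_seed)
            fprs.append(float((res["p"].to_numpy() < alpha).mean()))
        except Exception as exc:  # noqa: BLE001 - a broken permutation must not abort
            failures += 1
            log.warning("phenotype permutation %d failed: %s", i, exc)
    if failures:
        log.warning("%d of %d phenotype permutations failed", failures, n_label_perms)
    if not fprs:
        raise RuntimeError("every phenotype permutation failed")
    mean_fpr = float(np.mean(fprs))
    return mean_fpr, abs(mean_fpr - alpha)


# -- metric 4: reproducibility ----------------------------------------------

def reproducibility_auc(
    pipeline,
    study: PairedGenotypeStudy,
    n_subsets: int = 5,
    subset_size: int = 14,
    cutoffs=None,
    seed: int = 0,
) -> float:
    """AUC of the common-detection curve across disjoint subject subsets.

    Subjects are split into ``n_subsets`` disjoint groups of
    ``subset_size`` pairs; the pipeline runs once per group.  For each
    top-c cutoff the fraction ``|intersection of the groups' top-c set
    lists| / c`` is computed and averaged over the cutoff grid by the
    trapezoidal rule, yielding a value in [0, 1].
    """
    needed = n_subsets * subset_size
    if needed > study.n_pairs:
        raise ValueError(
            f"need at least {needed} subject pairs for {n_subsets} subsets "
            f"of {subset_size}; study has {study.n_pairs}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(study.n_pairs)
    rankings = []
    for i in range(n_subsets):
        rows = order[i * subset_size : (i + 1) * subset_size]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = pipeline(study.subset_subjects(np.sort(rows)), sub_seed)
        res = res.sort_values(["p", "set_id"], kind="stable")
        rankings.append(res["set_id"].tolist())
    n_sets = min(len(r) for r in rankings)
    if cutoffs is None:
        upper = max(2, n_sets // 2)
        cutoffs = np.unique(np.linspace(2, upper, num=10).astype(int))
    cutoffs = np.asarray(sorted(cutoffs))
    overlap = np.array([
        len(set.intersection(*(set(r[:c]) for r in rankings))) / c for c in cutoffs
    ])
    if cutoffs.size == 1:
        return float(overlap[0])
    return float(np.trapezoid(overlap, cutoffs) / (cutoffs[-1] - cutoffs[0]))


# -- report assembly and ranking --------------------------------------------

@dataclass
class BenchmarkReport:
    """The four metrics for one algorithm x integration x LD combination."""

    algorithm: str
    integration: str
    ld: bool
    sensitivity: float
    prioritization: float
    specificity_deviation: float
    reproducibility_auc: float


def evaluate_pipeline(
    pipeline: GsaPipeline,
    study: PairedGenotypeStudy,
    targets,
    seed: int = 0,
    n_label_perms: int = 50,
    n_subsets: int = 5,
    subset_size: int = 14,
) -> BenchmarkReport:
    """Compute all four metrics for one pipeline on one study."""
    res = pipeline(study, seed)
    sens = sensitivity_storey(res["p"].to_numpy())
    prio = prioritization(res, targets)
    _, spec_dev = specificity_fpr(pipeline, study, n_label_perms, seed=seed + 1)
    repro = reproducibility_auc(pipeline, study, n_subsets, subset_size, seed=seed + 2)
    return BenchmarkReport(
        pipeline.algorithm, pipeline.integration, pipeline.apply_ld,
        sens, prio, spec_dev, repro,
    )


_METRICS = {
    # metric column -> True when larger values are better
    "sensitivity": True,
    "prioritization": False,
    "specificity_deviation": False,
    "reproducibility_auc": True,
}


def reports_frame(reports: list[BenchmarkReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def normalize_and_rank(reports: pd.DataFrame, cluster: bool = True) -> pd.DataFrame:
    """Min-max normalize the metrics (best -> 0), rank combinations.

    Metrics where larger is better (sensitivity, reproducibility) are
    inverted before normalization so 0 is always the best observed value
    and 1 the worst.  The overall score sums the four normalized metrics;
    ranks are ascending with ties averaged.  When ``cluster`` is set and
    enough combinations exist, k-means labels (k chosen by silhouette) are
    attached -- a descriptive aid, not an inferential result.
    """
    if len(reports) < 2:
        raise ValueError("ranking needs at least two reports")
    out = reports.copy()
    for col, higher_better in _METRICS.items():
        x = out[col].to_numpy(dtype=float)
        span = x.max() - x.min()
        if span == 0:
            log.warning("metric %s is constant across reports; normalized to 0", col)
            out[f"norm_{col}"] = 0.0
            continue
        norm = (x.max() - x) / span if higher_better else (x - x.min()) / span
        out[f"norm_{col}"] = norm
    norm_cols = [f"norm_{c}" for c in _METRICS]
    out["overall_score"] = out[norm_cols].sum(axis=1)
    out["rank"] = stats.rankdata(out["overall_score"], method="average")
    out["cluster"] = _silhouette_kmeans(out[norm_cols].to_numpy()) if cluster else -1
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def _silhouette_kmeans(x: np.ndarray) -> np.ndarray:
    """Descriptive k-means labels with silhouette-selected k (or -1)."""
    n = x.shape[0]
    if n < 4 or np.allclose(x.std(axis=0).sum(), 0):
        return np.full(n, -1)
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    best_labels, best_score = None, -np.inf
    for k in range(2, min(6, n - 1) + 1):
        labels = KMeans(n_clusters=k, n_init=10, random_state=0).fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(x, labels)
        if score > best_score:
            best_labels, best_score = labels, score
    return best_labels if best_labels is not None else np.full(n, -1)
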