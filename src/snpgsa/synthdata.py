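"""Seeded generator of paired GWAS studies with LD and spiked gene sets.

The generator emulates the structure of a matched tumor/normal genotyping
study: 83 subject pairs by default, genotypes under the AA/AB/BB model,
within-gene linkage disequilibrium, and a gene set collection (341 sets,
54 of them phenotype targets by default) in which target sets are spiked
with genes that truly differ between the conditions.

Mechanics
---------
*Within-gene LD* comes from a Gaussian copula: each gene's SNPs share a
latent exchangeable-correlation normal vector (correlation ``ld_rho``)
thresholded at the Hardy-Weinberg genotype boundaries of a per-SNP allele
frequency, so normal-tissue genotype margins are exactly HWE.

*Concordance noise* uses a second, exchangeable latent draw for the tumor
condition (``z_t = sqrt(1 - tau) z_n + sqrt(tau) eta`` with ``eta`` an
independent copy of the gene's latent structure).  Because ``(z_n, z_t)``
is an exchangeable bivariate normal pair thresholded with identical
cutoffs, the genotype transition table is symmetric in distribution --
the paired symmetry test's null holds exactly when no effect is added.

*Association effects* shift the tumor genotype of affected SNPs one step
toward more alternate alleles (0->1->2, clipped) with probability
``effect_size`` per subject, creating exactly the marginal asymmetry the
paired test targets.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri

from .enrichment import GeneSetCollection
from .paired_association import PairedGenotypeStudy

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic paired-GWAS study.

    Defaults mirror the emulated study scale: 83 matched pairs, 341 gene
    sets of which 54 are targets.  ``effect_size`` is the per-subject
    probability that an associated SNP's tumor genotype moves one step up;
    ``target_effect_fraction`` is the fraction of each target set's genes
    drawn from the effect-gene pool.
    """

    n_pairs: int = 83
    n_genes: int = 500
    snps_per_gene: tuple[int, int] = (1, 10)
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    condition_noise: float = 0.05
    effect_size: float = 0.4
    n_effect_genes: int = 50
    n_gene_sets: int = 341
    n_target_sets: int = 54
    genes_per_set: tuple[int, int] = (10, 40)
    target_effect_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pairs, self.n_genes, self.n_gene_sets) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.n_target_sets > self.n_gene_sets:
            raise ValueError("target sets must be a subset of all sets")
        if self.n_effect_genes > self.n_genes:
            raise ValueError("more effect genes than genes")
        need = round(self.target_effect_fraction * self.genes_per_set[1])
        if need > self.n_effect_genes:
            raise ValueError(
                f"target sets may need {need} effect genes but the pool has "
                f"{self.n_effect_genes}"
            )
        if self.genes_per_set[1] > self.n_genes:
            raise ValueError("gene sets larger than the gene universe")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("snps_per_gene", "maf_range", "genes_per_set"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedTruth:
    """Ground truth of a simulated study, for benchmarking."""

    associated_snps: set[str] = field(default_factory=set)
    effect_genes: set[str] = field(default_factory=set)
    target_sets: set[str] = field(default_factory=set)


def _rng(seed: int, tag: str) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    return np.random.default_rng(ss)


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[PairedGenotypeStudy, pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Draw the paired genotype study plus SNP/gene annotation tables.

    Returns ``(study, snps, genes, truth)`` where ``snps`` has columns
    (snp_id, chrom, pos), ``genes`` has (gene_id, chrom, start, end,
    strand) with non-overlapping 10 kb bodies spaced far beyond the
    default mapping flank, and ``truth`` flags associated SNPs and effect
    genes (target sets are filled in by :func:`simulate_gene_sets`).
    """
    rng = _rng(config.seed, "genotypes")
    lo, hi = config.snps_per_gene
    snps_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)

    gene_len, spacing, per_chrom = 10_000, 100_000, 25
    gene_rows, snp_rows = [], []
    for i in range(config.n_genes):
        chrom = str(i // per_chrom + 1)
        start = 1 + (i % per_chrom) * spacing
        gene_rows.append((f"G{i:04d}", chrom, start, start + gene_len, "+"))
        m = snps_per_gene[i]
        offsets = np.sort(rng.choice(gene_len, size=m, replace=False))
        for j, off in enumerate(offsets):
            snp_rows.append((f"rs{i:04d}_{j}", chrom, start + int(off)))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])

    effect_idx = rng.choice(config.n_genes, size=config.n_effect_genes, replace=False)
    effect_genes = {f"G{i:04d}" for i in effect_idx}

    n, rho, tau = config.n_pairs, config.ld_rho, config.condition_noise
    a_cond = np.sqrt(1.0 - tau)
    cols_a, cols_b, associated = [], [], []
    for i in range(config.n_genes):
        m = snps_per_gene[i]
        q = rng.uniform(*config.maf_range, size=m)
        c0 = ndtri((1 - q) ** 2)
        c1 = ndtri((1 - q) ** 2 + 2 * q * (1 - q))

        def latent() -> np.ndarray:
            shared = rng.standard_normal((n, 1))
            return np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, m))

        z_n = latent()
        z_t = a_cond * z_n + np.sqrt(tau) * latent()
        g_n = ((z_n > c0).astype(np.int8) + (z_n > c1).astype(np.int8))
        g_t = ((z_t > c0).astype(np.int8) + (z_t > c1).astype(np.int8))
        if f"G{i:04d}" in effect_genes and config.effect_size > 0:
            shift = rng.random((n, m)) < config.effect_size
            g_t = np.minimum(g_t + shift.astype(np.int8), 2).astype(np.int8)
            associated.extend(f"rs{i:04d}_{j}" for j in range(m))
        cols_a.append(g_n)
        cols_b.append(g_t)

    study = PairedGenotypeStudy(
        subjects=[f"subj{j:03d}" for j in range(n)],
        snp_ids=snps["snp_id"].tolist(),
        condition_a=np.concatenate(cols_a, axis=1),
        condition_b=np.concatenate(cols_b, axis=1),
    )
    truth = SimulatedTruth(associated_snps=set(associated), effect_genes=effect_genes)
    log.info(
        "simulated %d pairs x %d SNPs in %d genes (%d effect genes)",
        n, study.n_snps, config.n_genes, len(effect_genes),
    )
    return study, snps, genes, truth


def simulate_gene_sets(
    config: SimulationConfig,
    gene_ids,
    truth: SimulatedTruth,
) -> GeneSetCollection:
    """Draw the gene set collection with spiked target sets.

    Target sets take ``target_effect_fraction`` of their members from the
    effect-gene pool (so they are truly enriched); background sets are
    uniform draws from all genes.  Set overlap is permitted.  Updates
    ``truth.target_sets`` in place.
    """
    rng = _rng(config.seed, "gene_sets")
    gene_ids = list(gene_ids)
    effect = sorted(truth.effect_genes)
    background = sorted(set(gene_ids) - truth.effect_genes)
    lo, hi = config.genes_per_set
    sets, descriptions, targets = {}, {}, set()
    for s in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if s < config.n_target_sets:
            name = f"T{s:03d}"
            n_eff = min(round(config.target_effect_fraction * size), len(effect))
            members = list(rng.choice(effect, size=n_eff, replace=False))
            members += list(rng.choice(background, size=size - n_eff, replace=False))
            targets.add(name)
            descriptions[name] = "target set (spiked with effect genes)"
        else:
            name = f"S{s:03d}"
            members = list(rng.choice(gene_ids, size=size, replace=False))
            descriptions[name] = "background set"
        sets[name] = members
    truth.target_sets = targets
    return GeneSetCollection(sets=sets, descriptions=descriptions, targets=targets)


@dataclass
class SyntheticStudy:
    """Bundle of one simulated study and everything downstream needs."""

    config: SimulationConfig
    study: PairedGenotypeStudy
    snps: pd.DataFrame
    genes: pd.DataFrame
    sets: GeneSetCollection
    truth: SimulatedTruth


def simulate(config: SimulationConfig) -> SyntheticStudy:
    """Full simulation: genotypes, annotations, and gene sets."""
    study, snps, genes, truth = simulate_genotypes(config)
    sets = simulate_gene_sets(config, genes["gene_id"].tolist(), truth)
    return SyntheticStudy(config, study, snps, genes, sets, truth)


#: configuration of the tiny deterministic fixture used in tests and docs
FIXTURE_CONFIG = SimulationConfig(
    n_pairs=24,
    n_genes=30,
    snps_per_gene=(1, 6),
    ld_rho=0.6,
    maf_range=(0.15, 0.5),
    condition_noise=0.08,
    effect_size=0.6,
    n_effect_genes=8,
    n_gene_sets=12,
    n_target_sets=2,
    genes_per_set=(5, 8),
    target_effect_fraction=1.0,
    seed=2021,
)


def small_fixture() -> SyntheticStudy:
    """Deterministic tiny study (<= 200 SNPs, 30 genes, 12 sets).

    Regenerating it always yields byte-identical arrays; it contains both
    single-SNP genes (k = 1 identity paths) and genes with k >= 5, and its
    two target sets are strongly spiked.
    """
    return simulate(FIXTURE_CONFIG)
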