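"""Paired genotype-phenotype association via an exact multinomial symmetry test.

Each subject contributes a genotype call (0/1/2 copies of the alternate
allele, i.e. AA/AB/BB) in two matched conditions (condition A = normal
tissue, condition B = tumor).  Per SNP the calls are tallied into a 3x3
transition table ``n[i, j]`` (genotype ``i`` in A, ``j`` in B) and tested
for marginal asymmetry with a Bowker-type symmetry statistic -- the
three-category extension of McNemar's test.  Significance is estimated by
Monte Carlo sampling from the exact conditional null: for every unordered
genotype pair the discordant subjects are redistributed as
Binomial(n_ij + n_ji, 1/2) while concordant (diagonal) counts stay fixed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: sentinel for a missing genotype call in the int8 matrices
MISSING = -1

#: unordered genotype pairs that can hold discordant subjects
_DISCORDANT_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass
class PairedGenotypeStudy:
    """Genotype calls for matched subject pairs (condition A vs condition B).

    Parameters
    ----------
    subjects : list of str
        Subject identifiers; each subject is observed in both conditions.
    snp_ids : list of str
        SNP identifiers (rsIDs), unique, column order of the matrices.
    condition_a, condition_b : ndarray of int8, shape (n_subjects, n_snps)
        Genotype calls coded 0/1/2; ``MISSING`` (-1) marks a failed call.
        Condition A is the reference condition (normal tissue), B the
        contrasted one (tumor).
    """

    subjects: list[str]
    snp_ids: list[str]
    condition_a: np.ndarray
    condition_b: np.ndarray

    def __post_init__(self) -> None:
        self.condition_a = np.asarray(self.condition_a, dtype=np.int8)
        self.condition_b = np.asarray(self.condition_b, dtype=np.int8)
        shape = (len(self.subjects), len(self.snp_ids))
        if self.condition_a.shape != shape or self.condition_b.shape != shape:
            raise ValueError(
                f"genotype matrices must have shape {shape} (subjects x SNPs)"
            )
        for name, mat in (("condition_a", self.condition_a), ("condition_b", self.condition_b)):
            bad = ~np.isin(mat, (MISSING, 0, 1, 2))
            if bad.any():
                raise ValueError(f"{name} contains codes outside {{0,1,2,missing}}")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_pairs(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_column(self, snp_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return the (condition A, condition B) genotype vectors of one SNP."""
        j = self._snp_index[snp_id]
        return self.condition_a[:, j], self.condition_b[:, j]

    def subset_snps(self, snp_ids: list[str]) -> "PairedGenotypeStudy":
        idx = [self._snp_index[s] for s in snp_ids]
        return PairedGenotypeStudy(
            self.subjects, list(snp_ids),
            self.condition_a[:, idx], self.condition_b[:, idx],
        )

    def subset_subjects(self, rows: np.ndarray) -> "PairedGenotypeStudy":
        rows = np.asarray(rows)
        return PairedGenotypeStudy(
            [self.subjects[i] for i in rows], list(self.snp_ids),
            self.condition_a[rows], self.condition_b[rows],
        )

    def swap_conditions(self, mask: np.ndarray) -> "PairedGenotypeStudy":
        """Return a copy with condition labels swapped where ``mask`` is True.

        This is the phenotype permutation consistent with the paired design:
        relabelling happens within a subject, never across subjects.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_pairs,):
            raise ValueError("mask must have one entry per subject")
        a = self.condition_a.copy()
        b = self.condition_b.copy()
        a[mask], b[mask] = self.condition_b[mask], self.condition_a[mask]
        return PairedGenotypeStudy(list(self.subjects), list(self.snp_ids), a, b)


@dataclass
class SnpAssociation:
    """Per-SNP result of the paired symmetry test."""

    snp_id: str
    statistic: float
    p_value: float
    n_effective: int
    error: str | None = None


def build_transition_table(study: PairedGenotypeStudy, snp_id: str) -> np.ndarray:
    """Tally the 3x3 genotype transition table of one SNP.

    Subjects with a missing call in either condition are dropped for this
    SNP.  Raises ``ValueError`` if no subject has both calls.
    """
    a, b = study.snp_column(snp_id)
    return _transition_table(a, b, snp_id)


def _transition_table(a: np.ndarray, b: np.ndarray, label: str = "") -> np.ndarray:
    keep = (a != MISSING) & (b != MISSING)
    if not keep.any():
        raise ValueError(f"SNP {label!r}: all subjects have a missing call")
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a[keep], b[keep]), 1)
    return table


def symmetry_statistic(table: np.ndarray) -> float:
    """Bowker symmetry statistic of a 3x3 transition table.

    Sum over unordered genotype pairs (i, j) with any discordance of
    ``(n_ij - n_ji)^2 / (n_ij + n_ji)``; pairs with zero discordance
    contribute nothing.  Zero iff the table is symmetric.
    """
    table = np.asarray(table)
    stat = 0.0
    for i, j in _DISCORDANT_PAIRS:
        d = table[i, j] + table[j, i]
        if d > 0:
            stat += (table[i, j] - table[j, i]) ** 2 / d
    return float(stat)


def monte_carlo_symmetry_test(
    table: np.ndarray,
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
    snp_id: str = "",
) -> SnpAssociation:
    """Monte Carlo p-value of the symmetry statistic.

    Null replicates redistribute each unordered pair's discordant subjects
    as Binomial(n_ij + n_ji, 1/2) with diagonal counts fixed; the p-value
    uses the add-one convention (b + 1) / (n_perm + 1), so it is never 0.
    A table with no discordant pair returns statistic 0 and p = 1 exactly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    table = np.asarray(table)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = symmetry_statistic(table)
    totals = [int(table[i, j] + table[j, i]) for i, j in _DISCORDANT_PAIRS]
    n_eff = int(table.sum())
    if sum(totals) == 0:
        return SnpAssociation(snp_id, 0.0, 1.0, n_eff)
    stats = np.zeros(n_perm)
    for t in totals:
        if t > 0:
            a = rng.binomial(t, 0.5, size=n_perm)
            stats += (2.0 * a - t) ** 2 / t
    exceed = int(np.count_nonzero(stats >= obs - 1e-9))
    p = (exceed + 1) / (n_perm + 1)
    return SnpAssociation(snp_id, obs, float(p), n_eff)


def snp_rng(master_seed: int, snp_id: str) -> np.random.Generator:
    """Reproducible per-SNP random stream, independent of execution order.

    The stream is keyed by (master seed, CRC32 of the rsID), so splitting
    the SNP list across workers or reordering it cannot change any p-value.
    """
    h = zlib.crc32(snp_id.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h])
    return np.random.default_rng(ss)


def associate_all(
    study: PairedGenotypeStudy,
    snp_ids: list[str] | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the paired symmetry test for every SNP of the study.

    Returns a DataFrame with columns ``snp_id, statistic, p_value,
    n_effective, error``.  A SNP whose table cannot be built (all calls
    missing) yields a flagged record with NaN p-value rather than aborting
    the run.
    """
    if snp_ids is None:
        snp_ids = list(study.snp_ids)
    records = []
    for snp in snp_ids:
        try:
            table = build_transition_table(study, snp)
        except ValueError as exc:
            log.warning("association skipped for %s: %s", snp, exc)
            records.append(SnpAssociation(snp, np.nan, np.nan, 0, error=str(exc)))
            continue
        rng = snp_rng(seed, snp)
        records.append(monte_carlo_symmetry_test(table, n_perm, rng, snp_id=snp))
    log.info("associated %d SNPs (%d failed)", len(records),
             sum(r.error is not None for r in records))
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "statistic": [r.statistic for r in records],
            "p_value": [r.p_value for r in records],
            "n_effective": [r.n_effective for r in records],
            "error": [r.error for r in records],
        }
    )
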