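"""Plain-text interchange formats: GMT gene sets, TSV tables, sidecars.

Everything the pipeline reads or writes is small derived text: genotype
matrices, SNP/gene annotation tables, association and gene-score tables,
and Broad-dialect GMT gene set files.  Every writer can attach a JSON
sidecar recording the tool version, a config hash and the master seed, so
any output table can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .paired_association import MISSING, PairedGenotypeStudy

log = logging.getLogger(__name__)


# -- GMT ---------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (name, description, members...).

    Duplicated members within a set are dropped with a warning; a line
    with fewer than three tab-separated fields raises an error naming the
    line.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members...), got {len(fields)}"
                )
            name, desc, *members = fields
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < len([m for m in members if m]):
                log.warning("%s:%d: set %s has duplicated members; deduplicated",
                            path, lineno, name)
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.description(name)
            fh.write("\t".join([name, desc, *members]) + "\n")


# -- genotype matrices -------------------------------------------------------

def write_genotypes(study: PairedGenotypeStudy, path) -> None:
    """Write the paired study as a long TSV: one row per subject x condition."""
    rows = []
    for cond, mat in (("A", study.condition_a), ("B", study.condition_b)):
        for i, subj in enumerate(study.subjects):
            rows.append([subj, cond, *mat[i]])
    df = pd.DataFrame(rows, columns=["subject_id", "condition", *study.snp_ids])
    df = df.replace(MISSING, pd.NA)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path) -> PairedGenotypeStudy:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "condition": str})
    required = {"subject_id", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: genotype TSV needs columns {sorted(required)}")
    conditions = set(df["condition"])
    if conditions != {"A", "B"}:
        raise ValueError(f"{path}: condition column must have levels A and B, got {sorted(conditions)}")
    snp_ids = [c for c in df.columns if c not in required]
    mats = {}
    for cond in ("A", "B"):
        sub = df[df["condition"] == cond].set_index("subject_id")
        mats[cond] = sub
    subjects = list(mats["A"].index)
    if set(subjects) != set(mats["B"].index):
        raise ValueError(f"{path}: every subject needs both conditions")
    a = mats["A"].loc[subjects, snp_ids].to_numpy(dtype=float)
    b = mats["B"].loc[subjects, snp_ids].to_numpy(dtype=float)
    a = np.where(np.isnan(a), MISSING, a).astype(np.int8)
    b = np.where(np.isnan(b), MISSING, b).astype(np.int8)
    return PairedGenotypeStudy(subjects, snp_ids, a, b)


# -- annotation tables -------------------------------------------------------

def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    _require(df, path, ("snp_id", "chrom", "pos"))
    return df


def read_gene_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    _require(df, path, ("gene_id", "chrom", "start", "end"))
    if "strand" not in df.columns:
        df["strand"] = "unknown"
    return df


def read_gff3_genes(path) -> pd.DataFrame:
    """Minimal GFF3 reader keeping only ``gene`` features.

    The gene identifier is taken from the ``ID=`` (or ``gene_id=``)
    attribute; coordinates stay 1-based closed as in GFF3.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line needs 9 fields")
            if fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("gene_id") or attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene feature lacks ID/gene_id")
            rows.append((gene_id, fields[0], int(fields[3]), int(fields[4]), fields[6]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _require(df: pd.DataFrame, path, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


# -- provenance sidecars -----------------------------------------------------

def write_table(df: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    """Write a result TSV; optionally attach a reproducibility sidecar."""
    df.to_csv(path, sep="\t", index=False)
    if sidecar is not None:
        write_sidecar(path, **sidecar)


def write_sidecar(path, **fields) -> None:
    """Write ``<path>.json`` with version, a config hash, and the fields."""
    from . import __version__

    payload = {"tool": "snpgsa", "version": __version__, **fields}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(fields, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    Path(str(path) + ".json").write_text(json.dumps(payload, indent=2, default=str) + "\n")
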