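"""Clonotype tables: reading, QC, aggregation, pooling, subsampling, writing.

A repertoire is one sample's TCRbeta clonotype table. Each row is a clonotype
(CDR3 amino-acid sequence, V/J gene call, read count); frequencies are always
recomputed from counts so that rounding in input files never propagates.

Supported dialects
------------------
``simple``      cdr3aa / v_gene / j_gene / count (tab-separated)
``airr``        AIRR-C rearrangement TSV: junction_aa / v_call / j_call / duplicate_count
``immunoseq``   Adaptive ImmunoSEQ-style export (read only); column names matched
                case-insensitively against a synonym list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import ArgumentError, EmptyRepertoireError, FormatError

logger = logging.getLogger(__name__)

#: canonical amino-acid alphabet for a functional CDR3
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_FUNCTIONAL_RE = re.compile(r"^[" + AA_ALPHABET + r"]{5,}$")

#: sentinel for a missing gene call; compares unequal to every named gene
MISSING_GENE = ""

COLUMNS = ["cdr3aa", "v_gene", "j_gene", "count", "frequency"]

ClonotypeKey = Literal["cdr3", "cdr3_v"]

# case-insensitive synonym lists for the ImmunoSEQ-style dialect
_IMMUNOSEQ_SYNONYMS = {
    "cdr3aa": ["amino_acid", "aminoacid", "cdr3_amino_acid", "aminoacid.beta"],
    "v_gene": ["v_gene", "vgenename", "v_resolved", "vmaxresolved"],
    "j_gene": ["j_gene", "jgenename", "j_resolved", "jmaxresolved"],
    "count": ["templates", "count (templates/reads)", "count", "reads", "count_templates_reads"],
    "frame": ["frame_type", "sequencestatus", "frame"],
}


@dataclass
class Clonotype:
    """One rearrangement record."""

    cdr3aa: str
    v_gene: str = MISSING_GENE
    j_gene: str = MISSING_GENE
    count: int = 0
    frequency: float = 0.0


@dataclass
class Repertoire:
    """A sample's clonotype table plus metadata.

    ``clonotypes`` is a DataFrame with columns cdr3aa, v_gene, j_gene, count,
    frequency (extra columns such as ``frame`` or ``specificity`` are carried
    through untouched). Frequencies sum to 1 whenever total count > 0.
    """

    sample_id: str
    clonotypes: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("cdr3aa", "v_gene", "j_gene", "count") if c not in self.clonotypes.columns]
        if missing:
            raise FormatError(f"clonotype table missing columns: {missing}")
        self.clonotypes = self.clonotypes.reset_index(drop=True)
        recompute_frequencies(self)

    # -- convenience accessors -------------------------------------------------
    @property
    def total_reads(self) -> int:
        return int(self.clonotypes["count"].sum())

    @property
    def richness(self) -> int:
        return len(self.clonotypes)

    @property
    def frequencies(self) -> np.ndarray:
        return self.clonotypes["frequency"].to_numpy()

    def keys(self, key: ClonotypeKey = "cdr3_v") -> pd.Series:
        return clonotype_keys(self.clonotypes, key)

    def copy(self, sample_id: str | None = None) -> "Repertoire":
        return Repertoire(sample_id or self.sample_id, self.clonotypes.copy(), dict(self.metadata))


def clonotype_keys(df: pd.DataFrame, key: ClonotypeKey) -> pd.Series:
    if key == "cdr3":
        return df["cdr3aa"].astype(str)
    if key == "cdr3_v":
        return df["cdr3aa"].astype(str) + "|" + df["v_gene"].astype(str)
    raise ArgumentError(f"unknown clonotype key {key!r}")


def recompute_frequencies(rep: Repertoire) -> None:
    total = rep.clonotypes["count"].sum()
    if total > 0:
        rep.clonotypes["frequency"] = rep.clonotypes["count"] / total
    else:
        rep.clonotypes["frequency"] = 0.0


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Iterable[str], dialect: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{dialect} table is missing mandatory column {c!r}")


def _resolve_immunoseq_columns(df: pd.DataFrame) -> dict:
    lower = {c.lower().strip(): c for c in df.columns}
    resolved = {}
    for target, synonyms in _IMMUNOSEQ_SYNONYMS.items():
        for syn in synonyms:
            if syn in lower:
                resolved[target] = lower[syn]
                break
    for mandatory in ("cdr3aa", "v_gene", "j_gene", "count"):
        if mandatory not in resolved:
            raise FormatError(
                f"immunoseq table is missing a column for {mandatory!r} "
                f"(accepted names: {_IMMUNOSEQ_SYNONYMS[mandatory]})"
            )
    return resolved


def read_clonotype_table(path, dialect: str = "simple") -> Repertoire:
    """Read a tab-separated clonotype table into a :class:`Repertoire`.

    Rows with an empty CDR3 are dropped (count logged); frequencies are
    recomputed from read counts regardless of any frequency column present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "simple":
        _require_columns(df, ["cdr3aa", "v_gene", "j_gene", "count"], dialect)
        out = df[["cdr3aa", "v_gene", "j_gene", "count"]].copy()
    elif dialect == "airr":
        _require_columns(df, ["junction_aa", "v_call", "j_call", "duplicate_count"], dialect)
        out = df[["junction_aa", "v_call", "j_call", "duplicate_count"]].copy()
        out.columns = ["cdr3aa", "v_gene", "j_gene", "count"]
    elif dialect == "immunoseq":
        resolved = _resolve_immunoseq_columns(df)
        out = pd.DataFrame(
            {
                "cdr3aa": df[resolved["cdr3aa"]],
                "v_gene": df[resolved["v_gene"]],
                "j_gene": df[resolved["j_gene"]],
                "count": df[resolved["count"]],
            }
        )
        if "frame" in resolved:
            out["frame"] = df[resolved["frame"]]
    else:
        raise ArgumentError(f"unknown dialect {dialect!r}")

    out["cdr3aa"] = out["cdr3aa"].fillna("").astype(str).str.strip()
    n_empty = int((out["cdr3aa"] == "").sum())
    if n_empty:
        logger.info("dropped %d rows with empty CDR3 from %s", n_empty, path)
        out = out[out["cdr3aa"] != ""]
    out["v_gene"] = out["v_gene"].fillna(MISSING_GENE).astype(str)
    out["j_gene"] = out["j_gene"].fillna(MISSING_GENE).astype(str)
    out["count"] = pd.to_numeric(out["count"], errors="raise").astype(int)
    if len(out) == 0 or out["count"].sum() == 0:
        raise EmptyRepertoireError(f"{path}: no reads after parsing")
    import os

    sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    return Repertoire(sample_id, out)


def write_clonotype_table(rep: Repertoire, path, dialect: str = "simple") -> None:
    """Write a repertoire so that :func:`read_clonotype_table` inverts it exactly."""
    if rep.richness == 0:
        raise ArgumentError("cannot write an empty repertoire")
    df = rep.clonotypes
    if dialect == "simple":
        out = df[["cdr3aa", "v_gene", "j_gene", "count"]]
    elif dialect == "airr":
        out = df[["cdr3aa", "v_gene", "j_gene", "count"]].copy()
        out.columns = ["junction_aa", "v_call", "j_call", "duplicate_count"]
    else:
        raise ArgumentError(f"unsupported output dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC / aggregation / pooling / subsampling
# ---------------------------------------------------------------------------

def is_functional(cdr3aa: str) -> bool:
    """True for an in-frame CDR3: >=5 residues over the 20-letter alphabet,
    no stop ('*') or frameshift ('_', '#') marks, no lowercase."""
    return bool(_FUNCTIONAL_RE.match(cdr3aa))


def filter_functional(rep: Repertoire) -> Repertoire:
    """Remove non-functional clonotypes and renormalize frequencies.

    Honors an ImmunoSEQ frame/productive column when present: rows not marked
    in-frame/productive are dropped as well. Idempotent.
    """
    df = rep.clonotypes
    keep = df["cdr3aa"].map(is_functional)
    if "frame" in df.columns:
        frame = df["frame"].astype(str).str.lower()
        keep &= frame.isin(["in", "in-frame", "inframe", "productive", "true", "t", "nan", ""]) | df["frame"].isna()
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_functional: removed %d of %d clonotypes", n_removed, len(df))
    survivors = df[keep].drop(columns=[c for c in ("frame",) if c in df.columns])
    if len(survivors) == 0:
        raise EmptyRepertoireError("all clonotypes removed by functional filter")
    return Repertoire(rep.sample_id, survivors.copy(), dict(rep.metadata))


def aggregate_duplicates(rep: Repertoire, key: ClonotypeKey = "cdr3_v") -> Repertoire:
    """Merge clonotypes identical under ``key``, summing counts.

    For the ``cdr3`` key the gene calls of the highest-count member are kept.
    """
    df = rep.clonotypes.sort_values("count", ascending=False, kind="stable")
    grouped = df.groupby(clonotype_keys(df, key), sort=False)
    merged = grouped.agg(
        cdr3aa=("cdr3aa", "first"),
        v_gene=("v_gene", "first"),
        j_gene=("j_gene", "first"),
        count=("count", "sum"),
    ).reset_index(drop=True)
    return Repertoire(rep.sample_id, merged, dict(rep.metadata))


def pool_repertoires(reps: list[Repertoire], new_id: str, key: ClonotypeKey = "cdr3_v") -> Repertoire:
    """Union of clonotypes with counts summed under ``key`` ('join samples')."""
    if not reps:
        raise ArgumentError("pool_repertoires requires at least one repertoire")
    df = pd.concat([r.clonotypes[["cdr3aa", "v_gene", "j_gene", "count"]] for r in reps], ignore_index=True)
    pooled = aggregate_duplicates(Repertoire(new_id, df), key=key)
    pooled.sample_id = new_id
    return pooled


def subsample_repertoire(rep: Repertoire, depth: int, seed: int) -> Repertoire:
    """Draw ``depth`` reads without replacement (multivariate hypergeometric)."""
    total = rep.total_reads
    if depth > total:
        raise ArgumentError(f"subsample depth {depth} exceeds total reads {total}")
    rng = np.random.default_rng(seed)
    counts = rng.multivariate_hypergeometric(rep.clonotypes["count"].to_numpy(), depth)
    df = rep.clonotypes[["cdr3aa", "v_gene", "j_gene"]].copy()
    df["count"] = counts
    df = df[df["count"] > 0]
    return Repertoire(rep.sample_id, df, dict(rep.metadata))
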