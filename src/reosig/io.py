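"""Reading, validation and harmonization of expression matrices and sample tables.

The in-memory representation of an expression matrix is a pandas DataFrame with
gene identifiers as the index and sample identifiers as the columns. A
distinction central to every downstream ordering rule is kept here: a literal
``0.0`` is a *measured* zero abundance, while ``NaN`` marks a gene that was not
measured in that sample (empty cell, or a gene absent from a dataset after
harmonization). The two are never conflated.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "validate_expression",
    "read_phenotype_table",
    "read_survival_table",
    "read_id_mapping",
    "map_gene_ids",
    "harmonize_gene_universe",
]

PHENOTYPE_GROUPS = frozenset({"normal", "IBD", "cancer"})
STAGES = frozenset({"I", "II", "III", "IV"})


def _detect_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants: unique ids, nonnegative values.

    Returns the matrix (float dtype) unchanged on success.
    """
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes}")
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("expression values must be nonnegative")
    return matrix.astype(float)


def read_expression_table(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a genes-in-rows delimited expression table.

    First column holds gene IDs, header row holds sample IDs. Empty cells
    become NaN (not measured); numeric cells are preserved exactly. The
    delimiter is inferred from the extension (.csv -> comma, otherwise tab)
    unless ``sep`` overrides it.
    """
    raw = pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0, dtype=str)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"malformed numeric cell at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        out[col] = converted
    return validate_expression(out)


def write_expression_table(matrix: pd.DataFrame, path: str, sep: str | None = None) -> None:
    """Write a matrix so that ``read_expression_table`` round-trips it.

    NaN (not measured) is written as an empty cell.
    """
    matrix.to_csv(path, sep=_detect_sep(path, sep), na_rep="")


def read_phenotype_table(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a sample phenotype table (sample_id, group, stage, relapse).

    ``group`` must be one of normal/IBD/cancer; ``stage`` (I-IV) may only be
    set for cancer samples.
    """
    pheno = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str)
    required = {"sample_id", "group"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    bad_groups = set(pheno["group"].dropna()) - PHENOTYPE_GROUPS
    if bad_groups:
        raise ValueError(f"unknown phenotype groups: {sorted(bad_groups)}")
    if "stage" in pheno.columns:
        staged = pheno["stage"].notna() & pheno["stage"].isin(STAGES)
        if (staged & (pheno["group"] != "cancer")).any():
            raise ValueError("stage may only be set for cancer samples")
    return pheno.set_index("sample_id", drop=False)


def read_survival_table(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read follow-up records (sample_id, time, event, optional covariates)."""
    surv = pd.read_csv(path, sep=_detect_sep(path, sep))
    missing = {"sample_id", "time", "event"} - set(surv.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if (surv["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return surv.set_index("sample_id", drop=False)


def read_id_mapping(path: str, sep: str | None = None) -> dict[str, set[str]]:
    """Read a two-column source->target gene-ID relation (one row per link)."""
    table = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str, header=None,
                        names=["source", "target"])
    mapping: dict[str, set[str]] = {}
    for source, target in zip(table["source"], table["target"]):
        mapping.setdefault(source, set())
        if pd.notna(target) and target != "":
            mapping[source].add(target)
    return mapping


def map_gene_ids(matrix: pd.DataFrame, mapping: Mapping[str, set[str] | frozenset[str]]) -> pd.DataFrame:
    """Translate gene identifiers through a source->targets relation.

    Source genes mapping to zero or multiple targets are deleted. When several
    sources map to one target, the target's value is the arithmetic mean of
    the source values per sample; a not-measured source is ignored in the mean
    unless every contributing source is not measured.
    """
    target_sources: dict[str, list[str]] = {}
    for gene in matrix.index:
        targets = mapping.get(gene, set())
        if len(targets) != 1:
            continue  # unmapped or ambiguous: deleted
        (target,) = targets
        target_sources.setdefault(target, []).append(gene)
    if not target_sources:
        raise ValueError("no genes survive ID mapping")
    rows = {}
    for target, sources in target_sources.items():
        block = matrix.loc[sources]
        # nan-aware mean: NaN only when all contributing sources are NaN
        rows[target] = block.mean(axis=0, skipna=True)
    mapped = pd.DataFrame(rows).T
    mapped.index.name = matrix.index.name
    mapped.columns = matrix.columns
    return validate_expression(mapped)


def harmonize_gene_universe(matrices: Iterable[pd.DataFrame]) -> list[pd.DataFrame]:
    """Reindex matrices onto the union of their gene sets.

    Genes absent from a dataset become NaN there — they behave downstream
    exactly like genes that were not measured. Sample order is preserved.
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to harmonize")
    union = matrices[0].index
    for m in matrices[1:]:
        union = union.union(m.index)
    return [m.reindex(union) for m in matrices]
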