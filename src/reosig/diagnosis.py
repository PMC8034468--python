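"""Early-diagnosis signature: rank-difference scoring, redundancy removal, voting.

The signature is a set of oriented gene pairs whose within-sample ordering
(gene_a > gene_b) is the cancer pattern. Candidate pairs are the stable
opposite pairs between cancer and normal training samples; each candidate is
scored by avgRD — the geometric mean of the absolute mean within-sample rank
differences in the two groups — and a greedy pass keeps, for every gene, only
its highest-scoring pair. A sample is called cancer when the retention rate of
the signature patterns reaches the voting cut-off (default 60%, inclusive).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import reo

__all__ = [
    "rank_transform",
    "rank_matrix",
    "rank_difference",
    "avg_rank_difference",
    "remove_redundant_pairs",
    "DiagnosisSignature",
    "build_diagnosis_signature",
    "classify_sample",
    "classify_samples",
    "evaluate_accuracy",
    "pool_counts",
]


def rank_transform(sample: pd.Series) -> pd.Series:
    """Ascending mid-ranks of the measured genes in one sample.

    Rank 1 is the lowest abundance; tied values receive the average of the
    ranks they span; genes that were not measured stay NaN and take no rank.
    """
    measured = sample.notna().sum()
    if measured < 2:
        raise ValueError("need at least two measured genes to rank")
    return sample.rank(method="average")


def rank_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample (column-wise) ascending mid-ranks over measured genes."""
    return matrix.rank(axis=0, method="average")


def rank_difference(ranks: pd.Series, pair: tuple[str, str]) -> float:
    """Signed rank difference rank(gene_a) - rank(gene_b); NaN if unranked."""
    gene_a, gene_b = pair
    r_a = ranks.get(gene_a, float("nan"))
    r_b = ranks.get(gene_b, float("nan"))
    return float(r_a - r_b)


def avg_rank_difference(
    pairs: pd.DataFrame | Iterable[tuple[str, str]],
    cancer_matrix: pd.DataFrame,
    cancer_samples: Sequence[str] | None,
    normal_matrix: pd.DataFrame,
    normal_samples: Sequence[str] | None,
) -> pd.DataFrame:
    """avgRD score per pair: sqrt(|mean RD in cancer| * |mean RD in normal|).

    Group means run over the samples where both genes are measured (ranked).
    Columns of the result: gene_a, gene_b, mean_rd_cancer, mean_rd_normal,
    avg_rd. Raises if a pair has no evaluable sample in either group.
    """
    if isinstance(pairs, pd.DataFrame):
        pair_list = list(zip(pairs["gene_a"], pairs["gene_b"]))
    else:
        pair_list = list(pairs)
    if not pair_list:
        raise ValueError("no pairs to score")

    def group_mean_rd(matrix: pd.DataFrame, samples: Sequence[str] | None) -> np.ndarray:
        sub = matrix if samples is None else matrix.loc[:, list(samples)]
        ranks = rank_matrix(sub).to_numpy(dtype=float)
        loc = {g: i for i, g in enumerate(matrix.index)}
        idx_a = np.array([loc[a] for a, _ in pair_list])
        idx_b = np.array([loc[b] for _, b in pair_list])
        rd = ranks[idx_a] - ranks[idx_b]  # pairs x samples, NaN where unranked
        n_ok = np.count_nonzero(~np.isnan(rd), axis=1)
        if np.any(n_ok == 0):
            bad = pair_list[int(np.argmax(n_ok == 0))]
            raise ValueError(f"pair {bad} has no evaluable sample in a group")
        return np.nanmean(rd, axis=1)

    mean_c = group_mean_rd(cancer_matrix, cancer_samples)
    mean_n = group_mean_rd(normal_matrix, normal_samples)
    return pd.DataFrame(
        {
            "gene_a": [a for a, _ in pair_list],
            "gene_b": [b for _, b in pair_list],
            "mean_rd_cancer": mean_c,
            "mean_rd_normal": mean_n,
            "avg_rd": np.sqrt(np.abs(mean_c) * np.abs(mean_n)),
        }
    )


def remove_redundant_pairs(scored: pd.DataFrame) -> pd.DataFrame:
    """Greedy redundancy removal: one pair per gene, best avgRD first.

    Scanning in descending avg_rd (ties broken by lexicographic gene_a then
    gene_b), a pair is kept iff neither gene already appears in a kept pair.
    """
    ordered = scored.sort_values(
        ["avg_rd", "gene_a", "gene_b"], ascending=[False, True, True]
    )
    used: set[str] = set()
    keep_rows = []
    for row in ordered.itertuples(index=False):
        if row.gene_a in used or row.gene_b in used:
            continue
        used.add(row.gene_a)
        used.add(row.gene_b)
        keep_rows.append(row)
    return pd.DataFrame(keep_rows, columns=ordered.columns)


@dataclasses.dataclass(frozen=True)
class DiagnosisSignature:
    """Oriented cancer-pattern pairs plus the retention-rate voting cut-off."""

    pairs: pd.DataFrame  # columns gene_a, gene_b (cancer pattern a > b), avg_rd
    vote_cutoff: float = 0.60
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.vote_cutoff < 1:
            raise ValueError("vote_cutoff must lie in (0, 1)")
        genes = pd.concat([self.pairs["gene_a"], self.pairs["gene_b"]])
        if genes.duplicated().any():
            raise ValueError("a gene may appear in at most one signature pair")

    def __len__(self) -> int:
        return len(self.pairs)


def build_diagnosis_signature(
    cancer_matrix: pd.DataFrame,
    cancer_samples: Sequence[str] | None,
    normal_matrix: pd.DataFrame,
    normal_samples: Sequence[str] | None,
    stable_threshold: float = 0.99,
    vote_cutoff: float = 0.60,
    max_genes: int = reo.DEFAULT_MAX_GENES,
) -> DiagnosisSignature:
    """Stable opposite pairs -> avgRD scoring -> redundancy removal -> signature.

    All surviving pairs are pooled into the signature, oriented to the cancer
    pattern (gene_a > gene_b in cancer).
    """
    candidates = reo.find_stable_opposite_pairs(
        cancer_matrix,
        cancer_samples,
        normal_matrix,
        normal_samples,
        threshold=stable_threshold,
        max_genes=max_genes,
    )
    if candidates.empty:
        raise ValueError("no stable opposite pairs at the requested threshold")
    scored = avg_rank_difference(
        candidates, cancer_matrix, cancer_samples, normal_matrix, normal_samples
    )
    kept = remove_redundant_pairs(scored)
    if kept.empty:
        raise ValueError("no pairs survive redundancy removal")
    n_cancer = cancer_matrix.shape[1] if cancer_samples is None else len(cancer_samples)
    n_normal = normal_matrix.shape[1] if normal_samples is None else len(normal_samples)
    return DiagnosisSignature(
        pairs=kept.reset_index(drop=True),
        vote_cutoff=vote_cutoff,
        meta={
            "stable_threshold": stable_threshold,
            "n_candidates": len(candidates),
            "n_cancer_samples": n_cancer,
            "n_normal_samples": n_normal,
        },
    )


def classify_sample(
    sample: pd.Series, signature: DiagnosisSignature
) -> tuple[str, reo.RetentionResult]:
    """Vote a single sample: CRC iff retention ratio >= vote_cutoff.

    The cut-off is inclusive. When no signature pair is evaluable the label is
    ``not_evaluable``.
    """
    result = reo.retention_rate(sample, signature.pairs)
    if not result.evaluable:
        return "not_evaluable", result
    label = "CRC" if result.ratio >= signature.vote_cutoff else "non_cancer"
    return label, result


def classify_samples(
    matrix: pd.DataFrame, signature: DiagnosisSignature
) -> pd.DataFrame:
    """Classify every column; returns sample_id, label, k, m, ratio."""
    rows = []
    for sample_id in matrix.columns:
        label, res = classify_sample(matrix[sample_id], signature)
        rows.append((sample_id, label, res.k, res.m, res.ratio))
    return pd.DataFrame(
        rows, columns=["sample_id", "label", "k", "m", "ratio"]
    ).set_index("sample_id", drop=False)


def evaluate_accuracy(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    signature: DiagnosisSignature,
) -> pd.DataFrame:
    """Per-group correct/total accuracy of the diagnosis vote.

    Cancer samples are correct when labelled CRC; normal and IBD samples when
    labelled non_cancer. Samples without a phenotype entry are skipped.
    Returns one row per group plus a pooled ``non_cancer`` row (normal + IBD)
    and an ``all`` row.
    """
    predictions = classify_samples(matrix, signature)
    counts: dict[str, list[int]] = {}
    for sample_id in matrix.columns:
        if sample_id not in phenotypes.index:
            continue
        group = phenotypes.loc[sample_id, "group"]
        expected = "CRC" if group == "cancer" else "non_cancer"
        correct = int(predictions.loc[sample_id, "label"] == expected)
        bucket = counts.setdefault(group, [0, 0])
        bucket[0] += correct
        bucket[1] += 1
    rows = []
    for group in sorted(counts):
        c, t = counts[group]
        rows.append((group, c, t, 100.0 * c / t))
    nc = [counts.get(g, [0, 0]) for g in ("normal", "IBD")]
    nc_correct, nc_total = sum(x[0] for x in nc), sum(x[1] for x in nc)
    if nc_total:
        rows.append(("non_cancer_pooled", nc_correct, nc_total, 100.0 * nc_correct / nc_total))
    all_correct = sum(x[0] for x in counts.values())
    all_total = sum(x[1] for x in counts.values())
    rows.append(("all", all_correct, all_total, 100.0 * all_correct / all_total))
    return pd.DataFrame(rows, columns=["group", "correct", "total", "accuracy_pct"])


def pool_counts(rows: Iterable[tuple[int, int]]) -> float:
    """Pooled percentage from per-dataset (correct, total) rows.

    Counts are summed before dividing, matching how multi-dataset accuracy
    totals are reported.
    """
    rows = list(rows)
    correct = sum(c for c, _ in rows)
    total = sum(t for _, t in rows)
    if total == 0:
        raise ValueError("no samples to pool")
    if any(c > t or c < 0 for c, t in rows):
        raise ValueError("correct counts must lie in [0, total]")
    return 100.0 * correct / total
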