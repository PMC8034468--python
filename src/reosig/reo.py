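"""Core relative-expression-ordering (REO) machinery.

The REO of a gene pair (i, j) within one sample is the order relation between
the two abundance values: G_i > G_j or G_i < G_j. Because it only uses the
within-sample ordering, it is invariant to any monotone per-sample distortion
of the measurements — the property that makes REO statistics usable on
degraded FFPE profiles and mixed-purity tumours.

Evaluability rules applied uniformly here and downstream:

* a pair is NOT evaluable in a sample when either gene is not measured (NaN),
  or when both measurements are exactly zero;
* a pair with exactly one zero IS evaluable (zero is a measured abundance);
* equal nonzero values are an evaluable tie — a tie never matches either
  directed pattern.

This module provides pair-sign evaluation, stable pairs within one group,
stable and significant opposite pairs between two groups (the latter via a
pooled hypergeometric reversal-enrichment tail with Benjamini-Hochberg FDR
control), and the retention rate of a signature's patterns in one sample.
"""

from __future__ import annotations

import enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Sign",
    "RetentionResult",
    "reo_sign",
    "pair_pattern_frequency",
    "all_gene_pairs",
    "find_stable_pairs",
    "find_stable_opposite_pairs",
    "opposite_pair_pvalue",
    "bh_adjust",
    "find_significant_opposite_pairs",
    "retention_rate",
]

#: Guardrail for exhaustive C(G, 2) pair scans; raise it deliberately for
#: larger gene universes (cost is quadratic in genes).
DEFAULT_MAX_GENES = 3000


class Sign(enum.Enum):
    GREATER = ">"
    LESS = "<"
    TIE = "="
    NOT_EVALUABLE = "NA"


class RetentionResult(NamedTuple):
    """Per-sample signature agreement: k of m evaluable pairs keep the pattern."""

    k: int
    m: int
    ratio: float

    @property
    def evaluable(self) -> bool:
        return self.m > 0


def reo_sign(x_a: float, x_b: float) -> Sign:
    """Order relation of two abundance values under the evaluability rules."""
    a = float("nan") if x_a is None else float(x_a)
    b = float("nan") if x_b is None else float(x_b)
    if (not np.isnan(a) and a < 0) or (not np.isnan(b) and b < 0):
        raise ValueError("abundance values must be nonnegative")
    if np.isnan(a) or np.isnan(b) or (a == 0 and b == 0):
        return Sign.NOT_EVALUABLE
    if a > b:
        return Sign.GREATER
    if a < b:
        return Sign.LESS
    return Sign.TIE


# ---------------------------------------------------------------------------
# vectorized pair counting


def _subset(matrix: pd.DataFrame, samples: Sequence[str] | None) -> np.ndarray:
    sub = matrix if samples is None else matrix.loc[:, list(samples)]
    if sub.shape[1] == 0:
        raise ValueError("sample subset is empty")
    values = sub.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("expression values must be nonnegative")
    return values


def _pair_counts(
    values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, chunk: int = 262144
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts of (GREATER, LESS, evaluable) per pair over samples.

    ``values`` is genes x samples with NaN for not-measured. Chunked over
    pairs to bound memory on full quadratic scans.
    """
    n_pairs = len(idx_a)
    greater = np.empty(n_pairs, dtype=np.int64)
    less = np.empty(n_pairs, dtype=np.int64)
    n_eval = np.empty(n_pairs, dtype=np.int64)
    for start in range(0, n_pairs, chunk):
        sl = slice(start, min(start + chunk, n_pairs))
        a = values[idx_a[sl]]
        b = values[idx_b[sl]]
        ok = ~(np.isnan(a) | np.isnan(b) | ((a == 0) & (b == 0)))
        greater[sl] = np.count_nonzero(ok & (a > b), axis=1)
        less[sl] = np.count_nonzero(ok & (a < b), axis=1)
        n_eval[sl] = np.count_nonzero(ok, axis=1)
    return greater, less, n_eval


def all_gene_pairs(genes: Sequence[str], max_genes: int = DEFAULT_MAX_GENES) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays for every unordered gene pair, with a size guardrail."""
    n = len(genes)
    if n > max_genes:
        raise ValueError(
            f"{n} genes would require {n * (n - 1) // 2} pairs; pass a "
            f"candidate pair list or raise max_genes explicitly"
        )
    idx_a, idx_b = np.triu_indices(n, k=1)
    return idx_a, idx_b


def _resolve_pairs(
    matrix: pd.DataFrame,
    candidate_pairs: Iterable[tuple[str, str]] | pd.DataFrame | None,
    max_genes: int,
) -> tuple[np.ndarray, np.ndarray]:
    if candidate_pairs is None:
        return all_gene_pairs(matrix.index, max_genes)
    if isinstance(candidate_pairs, pd.DataFrame):
        pairs = list(zip(candidate_pairs["gene_a"], candidate_pairs["gene_b"]))
    else:
        pairs = list(candidate_pairs)
    loc = {g: i for i, g in enumerate(matrix.index)}
    idx_a = np.array([loc[a] for a, _ in pairs], dtype=np.int64)
    idx_b = np.array([loc[b] for _, b in pairs], dtype=np.int64)
    if np.any(idx_a == idx_b):
        raise ValueError("a pair must consist of two distinct genes")
    return idx_a, idx_b


def pair_pattern_frequency(
    matrix: pd.DataFrame,
    samples: Sequence[str] | None,
    pair: tuple[str, str],
) -> tuple[float, int]:
    """Frequency of the directed pattern gene_a > gene_b among evaluable samples.

    Ties count against the pattern but remain evaluable. Returns
    ``(frequency, n_evaluable)``; frequency is NaN when no sample is evaluable.
    """
    values = _subset(matrix, samples)
    loc = {g: i for i, g in enumerate(matrix.index)}
    gene_a, gene_b = pair
    greater, _, n_eval = _pair_counts(
        values, np.array([loc[gene_a]]), np.array([loc[gene_b]])
    )
    if n_eval[0] == 0:
        return float("nan"), 0
    return greater[0] / n_eval[0], int(n_eval[0])


def _check_threshold(threshold: float) -> None:
    if not 0.5 < threshold <= 1.0:
        raise ValueError("stability threshold must lie in (0.5, 1] (orientation ambiguity below 0.5)")


def find_stable_pairs(
    matrix: pd.DataFrame,
    samples: Sequence[str] | None = None,
    threshold: float = 0.99,
    candidate_pairs: Iterable[tuple[str, str]] | pd.DataFrame | None = None,
    max_genes: int = DEFAULT_MAX_GENES,
) -> pd.DataFrame:
    """Pairs showing one REO direction in at least ``threshold`` of evaluable samples.

    Each unordered pair is emitted at most once, oriented to its majority
    direction (columns gene_a, gene_b mean gene_a > gene_b), with the attained
    frequency and evaluable sample count. The threshold is inclusive.
    """
    _check_threshold(threshold)
    values = _subset(matrix, samples)
    idx_a, idx_b = _resolve_pairs(matrix, candidate_pairs, max_genes)
    greater, less, n_eval = _pair_counts(values, idx_a, idx_b)
    with np.errstate(invalid="ignore"):
        freq_fwd = np.where(n_eval > 0, greater / np.maximum(n_eval, 1), np.nan)
        freq_rev = np.where(n_eval > 0, less / np.maximum(n_eval, 1), np.nan)
    keep_fwd = (n_eval > 0) & (freq_fwd >= threshold)
    keep_rev = (n_eval > 0) & (freq_rev >= threshold) & ~keep_fwd
    genes = matrix.index.to_numpy()
    out = pd.DataFrame(
        {
            "gene_a": np.concatenate([genes[idx_a[keep_fwd]], genes[idx_b[keep_rev]]]),
            "gene_b": np.concatenate([genes[idx_b[keep_fwd]], genes[idx_a[keep_rev]]]),
            "freq": np.concatenate([freq_fwd[keep_fwd], freq_rev[keep_rev]]),
            "n_evaluable": np.concatenate([n_eval[keep_fwd], n_eval[keep_rev]]),
        }
    )
    return out.sort_values(["gene_a", "gene_b"], ignore_index=True)


def find_stable_opposite_pairs(
    matrix_ref: pd.DataFrame,
    samples_ref: Sequence[str] | None,
    matrix_other: pd.DataFrame,
    samples_other: Sequence[str] | None,
    threshold: float = 0.99,
    candidate_pairs: Iterable[tuple[str, str]] | pd.DataFrame | None = None,
    max_genes: int = DEFAULT_MAX_GENES,
) -> pd.DataFrame:
    """Pairs stable in both groups with opposite directions.

    Oriented to the reference group's direction: gene_a > gene_b holds in at
    least ``threshold`` of evaluable reference samples while gene_a < gene_b
    holds in at least ``threshold`` of evaluable other-group samples.
    ``freq_other`` reports the other group's frequency of its own (reversed)
    direction.
    """
    _check_threshold(threshold)
    if list(matrix_ref.index) != list(matrix_other.index):
        raise ValueError("matrices must share a harmonized gene universe")
    vals_ref = _subset(matrix_ref, samples_ref)
    vals_other = _subset(matrix_other, samples_other)
    idx_a, idx_b = _resolve_pairs(matrix_ref, candidate_pairs, max_genes)
    g_ref, l_ref, n_ref = _pair_counts(vals_ref, idx_a, idx_b)
    g_oth, l_oth, n_oth = _pair_counts(vals_other, idx_a, idx_b)
    ok = (n_ref > 0) & (n_oth > 0)
    with np.errstate(invalid="ignore"):
        f_ref_fwd = g_ref / np.maximum(n_ref, 1)
        f_ref_rev = l_ref / np.maximum(n_ref, 1)
        f_oth_fwd = g_oth / np.maximum(n_oth, 1)
        f_oth_rev = l_oth / np.maximum(n_oth, 1)
    # reference says a > b, other says a < b — or the mirror image
    fwd = ok & (f_ref_fwd >= threshold) & (f_oth_rev >= threshold)
    rev = ok & (f_ref_rev >= threshold) & (f_oth_fwd >= threshold)
    genes = matrix_ref.index.to_numpy()
    out = pd.DataFrame(
        {
            "gene_a": np.concatenate([genes[idx_a[fwd]], genes[idx_b[rev]]]),
            "gene_b": np.concatenate([genes[idx_b[fwd]], genes[idx_a[rev]]]),
            "freq_ref": np.concatenate([f_ref_fwd[fwd], f_ref_rev[rev]]),
            "freq_other": np.concatenate([f_oth_rev[fwd], f_oth_fwd[rev]]),
        }
    )
    return out.sort_values(["gene_a", "gene_b"], ignore_index=True)


# ---------------------------------------------------------------------------
# reversal-enrichment test


def opposite_pair_pvalue(
    n_ref: int, k_ref_less: int, n_other: int, k_other_less: int
) -> float:
    """One-sided hypergeometric tail for reversal enrichment in the other group.

    Both groups' evaluable samples are pooled; conditioning on the total
    number of reversals (LESS outcomes for the reference orientation), the
    p-value is the probability that at least ``k_other_less`` of them land in
    the other group — the Fisher-style cumulative tail of the 2x2 table::

        [[n_ref - k_ref_less, k_ref_less],
         [n_other - k_other_less, k_other_less]]
    """
    if not (0 <= k_ref_less <= n_ref and 0 <= k_other_less <= n_other):
        raise ValueError("reversal counts must not exceed evaluable counts")
    if n_ref + n_other == 0:
        return 1.0
    total = n_ref + n_other
    reversals = k_ref_less + k_other_less
    return float(stats.hypergeom.sf(k_other_less - 1, total, reversals, n_other))


def _opposite_pair_pvalues(
    n_ref: np.ndarray, k_ref_less: np.ndarray, n_other: np.ndarray, k_other_less: np.ndarray
) -> np.ndarray:
    return stats.hypergeom.sf(
        k_other_less - 1, n_ref + n_other, k_ref_less + k_other_less, n_other
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def find_significant_opposite_pairs(
    matrix_ref: pd.DataFrame,
    samples_ref: Sequence[str] | None,
    matrix_other: pd.DataFrame,
    samples_other: Sequence[str] | None,
    fdr: float = 0.05,
    candidate_pairs: Iterable[tuple[str, str]] | pd.DataFrame | None = None,
    max_genes: int = DEFAULT_MAX_GENES,
) -> pd.DataFrame:
    """Pairs whose REO reverses between the groups at the given BH-FDR level.

    Every candidate pair evaluable in both groups is oriented to the
    reference group's majority direction and tested with
    :func:`opposite_pair_pvalue`; q-values are BH-adjusted across all tested
    pairs and pairs with q < fdr are returned.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    if list(matrix_ref.index) != list(matrix_other.index):
        raise ValueError("matrices must share a harmonized gene universe")
    vals_ref = _subset(matrix_ref, samples_ref)
    vals_other = _subset(matrix_other, samples_other)
    idx_a, idx_b = _resolve_pairs(matrix_ref, candidate_pairs, max_genes)
    g_ref, l_ref, n_ref = _pair_counts(vals_ref, idx_a, idx_b)
    g_oth, l_oth, n_oth = _pair_counts(vals_other, idx_a, idx_b)
    ok = (n_ref > 0) & (n_oth > 0)
    if not np.any(ok):
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "freq_ref", "freq_other", "p_value", "q_value"]
        )
    idx_a, idx_b = idx_a[ok], idx_b[ok]
    g_ref, l_ref, n_ref = g_ref[ok], l_ref[ok], n_ref[ok]
    g_oth, l_oth, n_oth = g_oth[ok], l_oth[ok], n_oth[ok]
    # orient each pair to the reference group's majority direction; because
    # the orientation is chosen from the same data, the one-sided tail is
    # doubled (union bound over the two orientations) to stay a valid p-value
    forward = g_ref >= l_ref
    k_ref_less = np.where(forward, l_ref, g_ref)
    k_oth_less = np.where(forward, l_oth, g_oth)
    p = np.minimum(1.0, 2.0 * _opposite_pair_pvalues(n_ref, k_ref_less, n_oth, k_oth_less))
    q = bh_adjust(p)
    keep = q < fdr
    genes = matrix_ref.index.to_numpy()
    out = pd.DataFrame(
        {
            "gene_a": np.where(forward, genes[idx_a], genes[idx_b])[keep],
            "gene_b": np.where(forward, genes[idx_b], genes[idx_a])[keep],
            "freq_ref": (np.where(forward, g_ref, l_ref) / n_ref)[keep],
            "freq_other": (k_oth_less / n_oth)[keep],
            "p_value": p[keep],
            "q_value": q[keep],
        }
    )
    return out.sort_values(["q_value", "gene_a", "gene_b"], ignore_index=True)


def retention_rate(
    sample: pd.Series,
    signature_pairs: pd.DataFrame | Iterable[tuple[str, str]],
) -> RetentionResult:
    """Fraction of evaluable signature pairs keeping the asserted pattern.

    ``m`` counts pairs evaluable in the sample (both genes measured, not both
    zero); ``k`` counts evaluable pairs where gene_a > gene_b holds. Pairs
    whose genes are absent from the sample index count as not measured. With
    m = 0 the result is not evaluable and carries a NaN ratio.
    """
    if isinstance(signature_pairs, pd.DataFrame):
        pairs = list(zip(signature_pairs["gene_a"], signature_pairs["gene_b"]))
    else:
        pairs = list(signature_pairs)
    if not pairs:
        raise ValueError("signature must contain at least one pair")
    values = sample.to_numpy(dtype=float)
    loc = {g: i for i, g in enumerate(sample.index)}
    nan = float("nan")
    a = np.array([values[loc[g]] if g in loc else nan for g, _ in pairs])
    b = np.array([values[loc[g]] if g in loc else nan for _, g in pairs])
    if np.nanmin(a, initial=0.0) < 0 or np.nanmin(b, initial=0.0) < 0:
        raise ValueError("abundance values must be nonnegative")
    ok = ~(np.isnan(a) | np.isnan(b) | ((a == 0) & (b == 0)))
    m = int(np.count_nonzero(ok))
    k = int(np.count_nonzero(ok & (a > b)))
    return RetentionResult(k, m, k / m if m else float("nan"))
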