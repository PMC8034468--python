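"""Rank-comparison differential expression (RankComp-style, single pass).

A gene's differential expression is inferred from disruptions of its stable
pairwise orderings rather than from its abundance: within each group the
significantly stable pairs are found with a one-sided exact binomial test
(null: either ordering equally likely), the two stable-pair lists are
intersected, and for every gene the 2x2 table of partners below/above it in
each group is tested with a two-sided Fisher exact test. Both test families
are Benjamini-Hochberg controlled (defaults: stable pairs at FDR < 20%, DEGs
at FDR < 5%).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import reo

__all__ = ["stable_pairs_binomial", "rankcomp_degs"]


def stable_pairs_binomial(
    matrix: pd.DataFrame,
    samples: Sequence[str] | None = None,
    fdr: float = 0.20,
    candidate_pairs: Iterable[tuple[str, str]] | pd.DataFrame | None = None,
    max_genes: int = reo.DEFAULT_MAX_GENES,
) -> pd.DataFrame:
    """Significantly stable pairs by an exact binomial tail with BH control.

    For each pair the one-sided tail P(X >= k_majority | n_evaluable, 1/2) is
    computed, q-values are BH-adjusted across all evaluable pairs, and pairs
    with q < fdr are returned oriented to the majority direction
    (gene_a > gene_b).
    """
    values = reo._subset(matrix, samples)
    idx_a, idx_b = reo._resolve_pairs(matrix, candidate_pairs, max_genes)
    greater, less, n_eval = reo._pair_counts(values, idx_a, idx_b)
    ok = n_eval > 0
    idx_a, idx_b = idx_a[ok], idx_b[ok]
    greater, less, n_eval = greater[ok], less[ok], n_eval[ok]
    k_major = np.maximum(greater, less)
    p = stats.binom.sf(k_major - 1, n_eval, 0.5)
    q = reo.bh_adjust(p)
    keep = q < fdr
    forward = greater >= less
    genes = matrix.index.to_numpy()
    out = pd.DataFrame(
        {
            "gene_a": np.where(forward, genes[idx_a], genes[idx_b])[keep],
            "gene_b": np.where(forward, genes[idx_b], genes[idx_a])[keep],
            "n_majority": k_major[keep],
            "n_evaluable": n_eval[keep],
            "p_value": p[keep],
            "q_value": q[keep],
        }
    )
    return out.sort_values(["gene_a", "gene_b"], ignore_index=True)


def _pair_key_frame(stable: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize an oriented stable-pair list: (lo_id, hi_id) key + which is higher."""
    a = stable["gene_a"].to_numpy()
    b = stable["gene_b"].to_numpy()
    first = np.minimum(a, b)
    second = np.maximum(a, b)
    return pd.DataFrame({"g1": first, "g2": second, "hi": a})


def rankcomp_degs(
    matrix_a: pd.DataFrame,
    samples_a: Sequence[str] | None,
    matrix_b: pd.DataFrame,
    samples_b: Sequence[str] | None,
    stable_fdr: float = 0.20,
    deg_fdr: float = 0.05,
    candidate_pairs: Iterable[tuple[str, str]] | pd.DataFrame | None = None,
    max_genes: int = reo.DEFAULT_MAX_GENES,
) -> pd.DataFrame:
    """REO-disruption DEGs between groups A and B.

    The partner universe is the intersection of the two groups' stable-pair
    lists. For each gene g, the table [[below_A, above_A], [below_B, above_B]]
    counts partners ordered below/above g in each group; a two-sided Fisher
    exact test with BH control flags DEGs. Direction is ``up`` when the
    fraction of partners below g rises in B. Genes with no stable partners in
    the shared universe are skipped.
    """
    stable_a = stable_pairs_binomial(
        matrix_a, samples_a, fdr=stable_fdr, candidate_pairs=candidate_pairs,
        max_genes=max_genes,
    )
    stable_b = stable_pairs_binomial(
        matrix_b, samples_b, fdr=stable_fdr, candidate_pairs=candidate_pairs,
        max_genes=max_genes,
    )
    if stable_a.empty or stable_b.empty:
        raise ValueError("no stable pairs in one of the groups")
    merged = _pair_key_frame(stable_a).merge(
        _pair_key_frame(stable_b), on=["g1", "g2"], suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("the two stable-pair lists do not overlap")
    # two rows per pair: one from each gene's point of view
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "gene": merged["g1"],
                    "below_a": (merged["hi_a"] == merged["g1"]).astype(int),
                    "below_b": (merged["hi_b"] == merged["g1"]).astype(int),
                }
            ),
            pd.DataFrame(
                {
                    "gene": merged["g2"],
                    "below_a": (merged["hi_a"] == merged["g2"]).astype(int),
                    "below_b": (merged["hi_b"] == merged["g2"]).astype(int),
                }
            ),
        ]
    )
    long["n"] = 1
    counts = long.groupby("gene").sum()
    rows = []
    for gene, row in counts.iterrows():
        a_below, b_below, n = int(row["below_a"]), int(row["below_b"]), int(row["n"])
        a_above, b_above = n - a_below, n - b_below
        p = stats.fisher_exact(
            [[a_below, a_above], [b_below, b_above]], alternative="two-sided"
        ).pvalue
        direction = "up" if b_below / n > a_below / n else "down"
        rows.append((gene, direction, p, a_below, a_above, b_below, b_above))
    result = pd.DataFrame(
        rows,
        columns=["gene", "direction", "p_value", "a_below", "a_above", "b_below", "b_above"],
    )
    result["q_value"] = reo.bh_adjust(result["p_value"])
    degs = result[result["q_value"] < deg_fdr]
    return degs.sort_values(["q_value", "gene"], ignore_index=True)[
        ["gene", "direction", "p_value", "q_value", "a_below", "a_above", "b_below", "b_above"]
    ]
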