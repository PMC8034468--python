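"""Relapse-risk signature: DEG-anchored reversed pairs, FFPE filter, selection.

Candidate pairs are the significant opposite pairs between stage IV
(metastatic) and stage I (non-metastatic) tumours that contain at least one
rank-disruption DEG, oriented to the stage-IV pattern. Candidates must keep
the same ordering in enough paired fresh-frozen / FFPE samples, are ranked by
the coverage difference C_IVI = C_IV - C_I, partitioned into candidate blocks
of 3500 + 1000*(n-1) pairs, and the block/cut-off combination is selected on
training accuracy. The relapse vote is strict: a sample is high risk when
*more than* the cut-off fraction (default 49%) of evaluable signature pairs
show the relapse pattern.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reo

__all__ = [
    "deg_anchored_opposite_pairs",
    "paired_concordance_filter",
    "coverage_difference",
    "sort_candidates",
    "partition_sizes",
    "partition_candidates",
    "RelapseSignature",
    "predict_relapse",
    "predict_samples",
    "select_relapse_signature",
]


def deg_anchored_opposite_pairs(
    stage_i_matrix: pd.DataFrame,
    stage_i_samples: Sequence[str] | None,
    stage_iv_matrix: pd.DataFrame,
    stage_iv_samples: Sequence[str] | None,
    degs: Iterable[str],
    fdr: float = 0.01,
    max_genes: int = reo.DEFAULT_MAX_GENES,
) -> pd.DataFrame:
    """Significant opposite pairs (stage IV vs I) containing at least one DEG.

    The candidate universe is every unordered pair with >= 1 gene in the DEG
    list; significance and orientation come from the reversal-enrichment test
    with stage IV as the reference group, so gene_a > gene_b is the stage-IV
    (relapse) pattern.
    """
    deg_set = set(degs)
    if not deg_set:
        raise ValueError("DEG list must be nonempty")
    genes = list(stage_iv_matrix.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    deg_idx = sorted(gene_pos[g] for g in deg_set if g in gene_pos)
    pairs = []
    deg_mask = np.zeros(len(genes), dtype=bool)
    deg_mask[deg_idx] = True
    for i in deg_idx:
        for j in range(len(genes)):
            if j == i or (deg_mask[j] and j < i):
                continue
            pairs.append((genes[min(i, j)], genes[max(i, j)]))
    result = reo.find_significant_opposite_pairs(
        stage_iv_matrix,
        stage_iv_samples,
        stage_i_matrix,
        stage_i_samples,
        fdr=fdr,
        candidate_pairs=pairs,
        max_genes=max_genes,
    )
    if result.empty:
        warnings.warn("no DEG-anchored significant opposite pairs found")
    return result


def paired_concordance_filter(
    pairs: pd.DataFrame,
    ff_matrix: pd.DataFrame,
    ffpe_matrix: pd.DataFrame,
    pairing: Mapping[str, str],
    min_concordant: int = 10,
) -> pd.DataFrame:
    """Keep gene pairs whose REO agrees in enough FF/FFPE sample pairs.

    For each gene pair, a sample pair is concordant when the ordering is
    evaluable in both the fresh-frozen and the FFPE member and identical
    between them. Gene pairs with at least ``min_concordant`` concordant
    sample pairs survive; the count is added as ``concordant_pairs``.
    """
    if not pairing:
        raise ValueError("FF/FFPE pairing must be nonempty")
    ff_ids = list(pairing.keys())
    ffpe_ids = [pairing[s] for s in ff_ids]
    loc = {g: i for i, g in enumerate(ff_matrix.index)}
    idx_a = np.array([loc[a] for a in pairs["gene_a"]], dtype=np.int64)
    idx_b = np.array([loc[b] for b in pairs["gene_b"]], dtype=np.int64)
    ff = ff_matrix.loc[:, ff_ids].to_numpy(dtype=float)
    fp = ffpe_matrix.loc[:, ffpe_ids].to_numpy(dtype=float)

    def signs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b = values[idx_a], values[idx_b]
        ok = ~(np.isnan(a) | np.isnan(b) | ((a == 0) & (b == 0)))
        # +1 / -1 / 0 encodes greater / less / tie
        return np.sign(a - b), ok

    s_ff, ok_ff = signs(ff)
    s_fp, ok_fp = signs(fp)
    concordant = np.count_nonzero(ok_ff & ok_fp & (s_ff == s_fp) & (s_ff != 0), axis=1)
    out = pairs.copy()
    out["concordant_pairs"] = concordant
    return out[out["concordant_pairs"] >= min_concordant].reset_index(drop=True)


def coverage_difference(
    pairs: pd.DataFrame,
    stage_iv_matrix: pd.DataFrame,
    stage_iv_samples: Sequence[str] | None,
    stage_i_matrix: pd.DataFrame,
    stage_i_samples: Sequence[str] | None,
) -> pd.DataFrame:
    """Coverage of the stage-IV pattern per group and their difference C_IVI.

    Coverage is the frequency of gene_a > gene_b among evaluable samples
    (both-zero samples are not counted). Columns added: coverage_iv,
    coverage_i, c_ivi; NaN when a group has no evaluable sample.
    """
    loc = {g: i for i, g in enumerate(stage_iv_matrix.index)}
    idx_a = np.array([loc[a] for a in pairs["gene_a"]], dtype=np.int64)
    idx_b = np.array([loc[b] for b in pairs["gene_b"]], dtype=np.int64)

    def coverage(matrix: pd.DataFrame, samples: Sequence[str] | None) -> np.ndarray:
        values = reo._subset(matrix, samples)
        greater, _, n_eval = reo._pair_counts(values, idx_a, idx_b)
        with np.errstate(invalid="ignore"):
            return np.where(n_eval > 0, greater / np.maximum(n_eval, 1), np.nan)

    out = pairs.copy()
    out["coverage_iv"] = coverage(stage_iv_matrix, stage_iv_samples)
    out["coverage_i"] = coverage(stage_i_matrix, stage_i_samples)
    out["c_ivi"] = out["coverage_iv"] - out["coverage_i"]
    return out


def sort_candidates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rank candidates: descending c_ivi, then descending coverage_iv, then genes."""
    return pairs.sort_values(
        ["c_ivi", "coverage_iv", "gene_a", "gene_b"],
        ascending=[False, False, True, True],
        ignore_index=True,
    )


def partition_sizes(n: int, base: int = 3500, step: int = 1000) -> list[int]:
    """Block sizes base, base+step, base+2*step, ... with the remainder last."""
    sizes: list[int] = []
    remaining = n
    k = 0
    while remaining > 0:
        nominal = base + step * k
        take = min(nominal, remaining)
        sizes.append(take)
        remaining -= take
        k += 1
    return sizes


def partition_candidates(
    sorted_pairs: pd.DataFrame, base: int = 3500, step: int = 1000
) -> list[pd.DataFrame]:
    """Split the ranked candidate list into consecutive candidate blocks."""
    sizes = partition_sizes(len(sorted_pairs), base=base, step=step)
    blocks = []
    start = 0
    for size in sizes:
        blocks.append(sorted_pairs.iloc[start : start + size].reset_index(drop=True))
        start += size
    return blocks


@dataclasses.dataclass(frozen=True)
class RelapseSignature:
    """One contiguous block of the ranked candidate list plus its strict cut-off."""

    pairs: pd.DataFrame
    block_index: int = 0
    vote_cutoff: float = 0.49
    meta: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def predict_relapse(
    sample: pd.Series, signature: RelapseSignature
) -> tuple[str, reo.RetentionResult]:
    """High risk iff strictly more than the cut-off fraction keep the pattern."""
    result = reo.retention_rate(sample, signature.pairs)
    if not result.evaluable:
        return "not_evaluable", result
    label = "high_risk" if result.ratio > signature.vote_cutoff else "low_risk"
    return label, result


def predict_samples(matrix: pd.DataFrame, signature: RelapseSignature) -> pd.DataFrame:
    rows = []
    for sample_id in matrix.columns:
        label, res = predict_relapse(matrix[sample_id], signature)
        rows.append((sample_id, label, res.k, res.m, res.ratio))
    return pd.DataFrame(
        rows, columns=["sample_id", "label", "k", "m", "ratio"]
    ).set_index("sample_id", drop=False)


def _block_ratios(
    block: pd.DataFrame, matrix: pd.DataFrame, samples: Sequence[str] | None
) -> np.ndarray:
    """Per-sample retention ratios of a block's patterns (NaN when inevaluable)."""
    sub = matrix if samples is None else matrix.loc[:, list(samples)]
    loc = {g: i for i, g in enumerate(sub.index)}
    idx_a = np.array([loc[a] for a in block["gene_a"]], dtype=np.int64)
    idx_b = np.array([loc[b] for b in block["gene_b"]], dtype=np.int64)
    values = sub.to_numpy(dtype=float)
    a, b = values[idx_a], values[idx_b]
    ok = ~(np.isnan(a) | np.isnan(b) | ((a == 0) & (b == 0)))
    m = ok.sum(axis=0)
    k = (ok & (a > b)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(m > 0, k / np.maximum(m, 1), np.nan)


def select_relapse_signature(
    blocks: Sequence[pd.DataFrame],
    stage_i_matrix: pd.DataFrame,
    stage_i_samples: Sequence[str] | None,
    stage_iv_matrix: pd.DataFrame,
    stage_iv_samples: Sequence[str] | None,
    cutoffs: Sequence[float] = (0.49, 0.50, 0.51),
    min_accuracy: float = 0.80,
) -> tuple[RelapseSignature, pd.DataFrame]:
    """Grid-evaluate (block, cutoff) on training stages and pick the signature.

    Stage-I accuracy is the fraction predicted low risk, stage-IV accuracy the
    fraction predicted high risk (micro-metastasis reading: stage IV carries
    the relapse pattern). The cut-off maximizing the mean stage-IV accuracy
    over blocks is chosen (ties -> smallest cut-off); among blocks whose two
    accuracies both exceed ``min_accuracy`` at that cut-off, the one with the
    most pairs wins. If no block passes, the block with the best worst-group
    accuracy is returned with a warning. The full grid is returned alongside.
    """
    if not blocks:
        raise ValueError("need at least one candidate block")
    grid_rows = []
    for bi, block in enumerate(blocks):
        ratios_i = _block_ratios(block, stage_i_matrix, stage_i_samples)
        ratios_iv = _block_ratios(block, stage_iv_matrix, stage_iv_samples)
        for cutoff in cutoffs:
            # stage I correct = low risk (ratio <= cutoff); stage IV = high risk
            acc_i = float(np.mean(ratios_i <= cutoff))  # NaN compares False
            acc_iv = float(np.mean(ratios_iv > cutoff))
            grid_rows.append((bi, len(block), cutoff, acc_i, acc_iv))
    grid = pd.DataFrame(
        grid_rows, columns=["block", "n_pairs", "cutoff", "acc_stage_i", "acc_stage_iv"]
    )
    by_cutoff = grid.groupby("cutoff")["acc_stage_iv"].mean()
    best_cutoff = float(by_cutoff.index[np.argmax(by_cutoff.to_numpy())])
    at_cutoff = grid[grid["cutoff"] == best_cutoff]
    passing = at_cutoff[
        (at_cutoff["acc_stage_i"] > min_accuracy)
        & (at_cutoff["acc_stage_iv"] > min_accuracy)
    ]
    if not passing.empty:
        chosen = passing.sort_values(["n_pairs", "block"], ascending=False).iloc[0]
    else:
        warnings.warn("no candidate block exceeds the accuracy floor in both stages")
        worst = at_cutoff[["acc_stage_i", "acc_stage_iv"]].min(axis=1)
        chosen = at_cutoff.loc[worst.idxmax()]
    block_index = int(chosen["block"])
    signature = RelapseSignature(
        pairs=blocks[block_index].reset_index(drop=True),
        block_index=block_index,
        vote_cutoff=best_cutoff,
        meta={
            "acc_stage_i": float(chosen["acc_stage_i"]),
            "acc_stage_iv": float(chosen["acc_stage_iv"]),
            "n_blocks": len(blocks),
        },
    )
    return signature, grid
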