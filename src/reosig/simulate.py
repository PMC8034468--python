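"""Synthetic cohorts with planted REO structure and FFPE-style degradation.

The generator emulates the statistical structure the REO analyses assume,
with full ground truth for parameter-recovery tests:

* **Planted diagnosis pairs.** Each pair has two log-expression levels
  (centre +/- half-gap) that swap between the normal and cancer groups, so
  the pair's ordering reverses completely. Pair centres sit on a spaced grid
  and background gene means are rejection-sampled outside the pair windows,
  so on noise-free data the stable opposite pairs between cancer and normal
  are exactly the planted ones.
* **Planted relapse pairs / stage-dependent DEGs.** Each relapse gene swings
  between a low and a high state (centre +/- shift) with per-sample Bernoulli
  probability (1-gap)/2 in stage I (and latent low-risk stage II/III tumours)
  versus (1+gap)/2 in stage IV (and latent high-risk tumours), so the
  coverage difference of the pair against its fixed partner equals the
  configured gap in expectation, and the swing disrupts the gene's orderings
  against every gene inside its window (a rank-shift DEG). Normal and IBD
  samples hold the low state.
* **IBD.** Normal-like profiles with a tiny non-reversing per-gene
  perturbation, so colitis classifies as non-cancer.
* **FFPE degradation.** Zero-inflation with dropout probability increasing
  as expression decreases (logistic in log-expression), calibrated so the
  expected zero fraction matches the requested rate, plus optional
  multiplicative log-normal noise on the surviving values.
* **Tumour purity.** Cancer profiles are convex mixtures of the tumour
  profile and the noise-free normal consensus; with tumour fraction above
  one half, planted orderings are preserved.
* **Relapse-linked survival.** Exponential event times whose hazard is
  multiplied by a true hazard ratio in latent high-risk samples, with
  independent exponential censoring calibrated to the requested censoring
  fraction.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "simulate_cohort",
    "apply_ffpe_degradation",
    "mix_purity",
    "simulate_survival",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Cohort layout and noise model; defaults are the package's study conditions."""

    n_genes: int = 300
    n_normal: int = 40
    n_ibd: int = 20
    n_stage_i: int = 40
    n_stage_ii: int = 20
    n_stage_iii: int = 20
    n_stage_iv: int = 40
    frac_high_risk: float = 0.5  # latent high-risk fraction among stage II/III
    n_planted_diag_pairs: int = 12
    diag_pair_gap: float = 0.5  # half-gap d of the swapped levels (log scale)
    diag_grid_start: float = 0.0  # lowest pair centre (log scale)
    n_planted_relapse_pairs: int = 30
    relapse_shift: float = 1.5  # half-swing of a relapse gene (log scale)
    planted_coverage_gap: float = 0.6  # target C_IVI of planted relapse pairs
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.2
    noise_sd: float = 0.2  # per-measurement log-normal noise
    dropout_rate: float = 0.3  # zero fraction applied to the cohort matrix
    dropout_bias: float = 6.0  # logistic steepness towards low expression
    # tumour-fraction range of the cohort's cancer columns; the default keeps
    # them unmixed (research-grade resections) — low-purity application
    # profiles are made explicitly with mix_purity
    purity_alpha: tuple[float, float] = (1.0, 1.0)
    n_ff_ffpe_pairs: int = 13
    ffpe_dropout_rate: float = 0.35
    ffpe_noise_sd: float = 0.5
    baseline_hazard: float = 0.02  # events per month, low-risk group
    true_hr: float = 3.0
    censoring_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        planted_genes = 2 * (self.n_planted_diag_pairs + self.n_planted_relapse_pairs)
        if planted_genes > self.n_genes:
            raise ValueError(
                f"{planted_genes} planted genes exceed the {self.n_genes}-gene universe"
            )
        for name in ("frac_high_risk", "dropout_rate", "ffpe_dropout_rate", "censoring_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.planted_coverage_gap <= 1:
            raise ValueError("planted_coverage_gap must lie in [0, 1]")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        sizes = (self.n_normal, self.n_ibd, self.n_stage_i, self.n_stage_ii,
                 self.n_stage_iii, self.n_stage_iv)
        if any(s < 0 for s in sizes) or sum(sizes) == 0:
            raise ValueError("group sizes must be nonnegative with at least one sample")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What was planted, for recovery tests."""

    diag_pairs: list[tuple[str, str]]  # oriented: gene_a > gene_b in cancer
    relapse_pairs: list[tuple[str, str]]  # oriented: gene_a > gene_b in stage IV
    deg_genes: list[str]  # relapse genes, direction up in stage IV
    high_risk: dict[str, bool]  # latent risk per stage II/III sample
    purity: dict[str, float]  # tumour fraction per cancer sample


@dataclasses.dataclass(frozen=True)
class Cohort:
    expression: pd.DataFrame  # degraded (dropout applied) matrix
    clean_expression: pd.DataFrame  # pre-dropout matrix
    phenotype: pd.DataFrame
    survival: pd.DataFrame  # stage II/III follow-up
    ff: pd.DataFrame  # paired fresh-frozen profiles
    ffpe: pd.DataFrame  # degraded versions of the same samples
    pairing: dict[str, str]  # FF sample id -> FFPE sample id
    ground_truth: GroundTruth
    config: SimulationConfig


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def apply_ffpe_degradation(
    matrix: pd.DataFrame,
    dropout_rate: float,
    bias_strength: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Zero-inflate a matrix the way degraded FFPE profiles are zero-inflated.

    Each measured nonzero value is set to zero with probability
    sigmoid(bias_strength * (threshold - log value)); the threshold is
    calibrated by bisection so the expected overall zero fraction (existing
    zeros included) equals ``dropout_rate``. Surviving values are multiplied
    by log-normal noise with the given log-scale sd. Not-measured entries are
    untouched. Deterministic under ``seed``.
    """
    if not 0 <= dropout_rate <= 1:
        raise ValueError("dropout_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy(dtype=float).copy()
    finite = ~np.isnan(values)
    nonzero = finite & (values > 0)
    n_finite = int(finite.sum())
    n_zero = int((finite & (values == 0)).sum())
    target_drops = dropout_rate * n_finite - n_zero
    if target_drops > 0 and nonzero.any():
        target_mean = min(1.0, target_drops / nonzero.sum())
        logx = np.log(values[nonzero])
        if bias_strength == 0:
            p = np.full(logx.shape, target_mean)
        else:
            lo, hi = logx.min() - 50.0 / bias_strength, logx.max() + 50.0 / bias_strength
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                if _sigmoid(bias_strength * (mid - logx)).mean() < target_mean:
                    lo = mid
                else:
                    hi = mid
            p = _sigmoid(bias_strength * (0.5 * (lo + hi) - logx))
        drop = rng.random(p.shape) < p
        kept = values[nonzero]
        kept[drop] = 0.0
        values[nonzero] = kept
    if noise_sd > 0:
        survivors = finite & (values > 0)
        values[survivors] *= np.exp(rng.normal(0.0, noise_sd, survivors.sum()))
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def mix_purity(
    tumor_profile: pd.Series | pd.DataFrame,
    normal_profile: pd.Series | pd.DataFrame,
    alpha: float,
) -> pd.Series | pd.DataFrame:
    """Convex mixture alpha * tumour + (1 - alpha) * normal, gene by gene."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if not tumor_profile.index.equals(normal_profile.index):
        raise ValueError("profiles must share the same gene universe")
    return alpha * tumor_profile + (1 - alpha) * normal_profile


def simulate_survival(
    high_risk: Sequence[bool],
    baseline_hazard: float = 0.02,
    true_hr: float = 3.0,
    censoring_rate: float = 0.2,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exponential event times with hazard scaled by ``true_hr`` for high risk.

    Censoring times are independent exponentials with per-subject rate
    hazard * q / (1 - q), which makes the expected censored fraction exactly
    ``censoring_rate``; with rate 0 all events are observed.
    """
    if true_hr <= 0:
        raise ValueError("true_hr must be positive")
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    risk = np.asarray(list(high_risk), dtype=bool)
    hazard = np.where(risk, baseline_hazard * true_hr, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        cens_rate = hazard * censoring_rate / (1.0 - censoring_rate)
        cens_time = rng.exponential(1.0 / cens_rate)
    else:
        cens_time = np.full_like(event_time, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(len(risk))]
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "time": time,
            "event": event,
            "risk_group": np.where(risk, "high_risk", "low_risk"),
        }
    ).set_index("sample_id", drop=False)


def _sample_ids(config: SimulationConfig) -> dict[str, list[str]]:
    groups = {
        "normal": config.n_normal,
        "IBD": config.n_ibd,
        "I": config.n_stage_i,
        "II": config.n_stage_ii,
        "III": config.n_stage_iii,
        "IV": config.n_stage_iv,
    }
    ids = {}
    for name, n in groups.items():
        ids[name] = [f"{name}_{i:03d}" for i in range(n)]
    return ids


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> Cohort:
    """Generate a full cohort (expression, phenotype, survival, FF/FFPE pairs).

    Keyword overrides are applied on top of ``config`` (or the defaults).
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    n_diag, n_rel = config.n_planted_diag_pairs, config.n_planted_relapse_pairs
    diag_hi = perm[:n_diag]
    diag_lo = perm[n_diag : 2 * n_diag]
    rel_gene = perm[2 * n_diag : 2 * n_diag + n_rel]
    rel_partner = perm[2 * n_diag + n_rel : 2 * n_diag + 2 * n_rel]
    background = perm[2 * n_diag + 2 * n_rel :]

    d = config.diag_pair_gap
    spacing = 2.4 * d
    centres = config.diag_grid_start + spacing * np.arange(n_diag)
    windows = [(c - 1.1 * d, c + 1.1 * d) for c in centres]

    def outside_windows(size: int, offsets: tuple[float, ...] = (0.0,)) -> np.ndarray:
        # rejection-sample log-means so that every listed offset of the draw
        # avoids all diagnosis-pair windows (keeps the planted reversals the
        # only stable opposite structure on noise-free data)
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size)
            ok = np.ones(len(draw), dtype=bool)
            for lo, hi in windows:
                for off in offsets:
                    ok &= ~((draw + off > lo) & (draw + off < hi))
            take = draw[ok][: size - filled]
            out[filled : filled + len(take)] = take
            filled += len(take)
        return out

    mu_background = outside_windows(len(background))
    # a relapse gene's centre (= its partner's level) and both swing states
    # must all clear the diagnosis windows
    mu_rel_centre = outside_windows(
        n_rel, offsets=(0.0, -config.relapse_shift, config.relapse_shift)
    )
    # the partner sits at the swing centre, so the pair's ordering follows the
    # relapse gene's state and its coverage difference equals the planted gap
    mu_partner = mu_rel_centre.copy()

    ids = _sample_ids(config)
    normal_like = ids["normal"] + ids["IBD"]
    cancer_ids = ids["I"] + ids["II"] + ids["III"] + ids["IV"]
    all_ids = normal_like + cancer_ids
    n_samples = len(all_ids)
    col = {s: j for j, s in enumerate(all_ids)}

    # latent high-risk assignment for stage II/III
    high_risk: dict[str, bool] = {}
    for stage in ("II", "III"):
        samples = ids[stage]
        n_high = int(round(config.frac_high_risk * len(samples)))
        flags = np.zeros(len(samples), dtype=bool)
        flags[:n_high] = True
        rng.shuffle(flags)
        for s, f in zip(samples, flags):
            high_risk[s] = bool(f)

    # log-mean matrix
    M = np.empty((config.n_genes, n_samples))
    M[background, :] = mu_background[:, None]
    M[rel_partner, :] = mu_partner[:, None]

    is_cancer = np.zeros(n_samples, dtype=bool)
    for s in cancer_ids:
        is_cancer[col[s]] = True
    # diagnosis pairs: swapped levels between normal-like and cancer samples
    for k in range(n_diag):
        hi_cancer, lo_cancer = centres[k] + d, centres[k] - d
        M[diag_hi[k], :] = np.where(is_cancer, hi_cancer, lo_cancer)
        M[diag_lo[k], :] = np.where(is_cancer, lo_cancer, hi_cancer)

    # relapse genes: Bernoulli high/low state per sample
    p_low = (1.0 - config.planted_coverage_gap) / 2.0
    p_high = (1.0 + config.planted_coverage_gap) / 2.0
    state_p = np.zeros(n_samples)  # normal/IBD stay in the low state
    for s in ids["I"]:
        state_p[col[s]] = p_low
    for stage in ("II", "III"):
        for s in ids[stage]:
            state_p[col[s]] = p_high if high_risk[s] else p_low
    for s in ids["IV"]:
        state_p[col[s]] = p_high
    delta = config.relapse_shift
    for k in range(n_rel):
        states = rng.random(n_samples) < state_p
        M[rel_gene[k], :] = np.where(states, mu_rel_centre[k] + delta,
                                     mu_rel_centre[k] - delta)

    # IBD: tiny non-reversing per-gene perturbation of the normal profile
    ibd_jitter = rng.uniform(-0.01, 0.01, config.n_genes)
    for s in ids["IBD"]:
        M[:, col[s]] += ibd_jitter

    logX = M + (rng.normal(0.0, config.noise_sd, M.shape) if config.noise_sd > 0 else 0.0)
    X = np.exp(logX)

    # tumour purity: mix cancer columns with the noise-free normal consensus
    normal_consensus = np.exp(M[:, col[ids["normal"][0]]]) if ids["normal"] else None
    purity: dict[str, float] = {}
    lo_a, hi_a = config.purity_alpha
    for s in cancer_ids:
        alpha = float(rng.uniform(lo_a, hi_a))
        purity[s] = alpha
        if normal_consensus is not None and alpha < 1.0:
            X[:, col[s]] = alpha * X[:, col[s]] + (1 - alpha) * normal_consensus

    clean = pd.DataFrame(X, index=genes, columns=all_ids)

    # paired FF/FFPE samples, drawn from stage II/III tumours
    ff_pool = ids["II"] + ids["III"] + ids["IV"]
    if config.n_ff_ffpe_pairs > len(ff_pool):
        raise ValueError("not enough tumour samples for the requested FF/FFPE pairs")
    ff_source = list(rng.choice(ff_pool, size=config.n_ff_ffpe_pairs, replace=False))
    ff = clean[ff_source].copy()
    ff.columns = [f"FF_{s}" for s in ff_source]
    ffpe = apply_ffpe_degradation(
        clean[ff_source],
        config.ffpe_dropout_rate,
        bias_strength=config.dropout_bias,
        noise_sd=config.ffpe_noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    ffpe.columns = [f"FFPE_{s}" for s in ff_source]
    pairing = dict(zip(ff.columns, ffpe.columns))

    if config.dropout_rate > 0:
        expression = apply_ffpe_degradation(
            clean,
            config.dropout_rate,
            bias_strength=config.dropout_bias,
            noise_sd=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
    else:
        expression = clean.copy()

    pheno_rows = []
    for s in ids["normal"]:
        pheno_rows.append((s, "normal", None, None))
    for s in ids["IBD"]:
        pheno_rows.append((s, "IBD", None, None))
    for stage in ("I", "II", "III", "IV"):
        for s in ids[stage]:
            relapse = None
            if stage in ("II", "III"):
                relapse = "relapse" if high_risk[s] else "non_relapse"
            pheno_rows.append((s, "cancer", stage, relapse))
    phenotype = pd.DataFrame(
        pheno_rows, columns=["sample_id", "group", "stage", "relapse"]
    ).set_index("sample_id", drop=False)

    followup_ids = ids["II"] + ids["III"]
    survival = simulate_survival(
        [high_risk[s] for s in followup_ids],
        baseline_hazard=config.baseline_hazard,
        true_hr=config.true_hr,
        censoring_rate=config.censoring_rate,
        seed=int(rng.integers(2**31 - 1)),
        sample_ids=followup_ids,
    )

    truth = GroundTruth(
        diag_pairs=[(genes[diag_hi[k]], genes[diag_lo[k]]) for k in range(n_diag)],
        relapse_pairs=[(genes[rel_gene[k]], genes[rel_partner[k]]) for k in range(n_rel)],
        deg_genes=[genes[i] for i in rel_gene],
        high_risk=high_risk,
        purity=purity,
    )
    return Cohort(
        expression=expression,
        clean_expression=clean,
        phenotype=phenotype,
        survival=survival,
        ff=ff,
        ffpe=ffpe,
        pairing=pairing,
        ground_truth=truth,
        config=config,
    )
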