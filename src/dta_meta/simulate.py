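"""Synthetic meta-analysis panels with known truth.

Per-study accuracy is drawn on the logit scale from a bivariate normal
(between-study heterogeneity, with an optional sensitivity/FPR correlation
acting as a threshold-effect knob), cell counts follow binomial within-study
sampling, and an optional small-study effect shifts each study's log
diagnostic odds ratio by ``bias_strength / sqrt(ESS)``.  A single integer
seed fully determines a panel; per-study sub-streams are spawned
deterministically so panels are stable under study-count changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bias import effective_sample_size
from .errors import ValidationError
from .studies import StudyRecord

__all__ = ["SynthConfig", "generate_panel", "generate_paired_panel", "logit", "inv_logit"]


def logit(p: float) -> float:
    if not 0 < p < 1:
        raise ValidationError(f"logit needs p in (0, 1), got {p}")
    return math.log(p / (1 - p))


def inv_logit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class SynthConfig:
    """Data-generating parameters for one synthetic test arm."""

    k: int = 8
    mu_sens: float = logit(0.90)
    mu_spec: float = logit(0.95)
    tau_sens: float = 0.3
    tau_spec: float = 0.3
    rho_threshold: float = 0.0
    prevalence: float = 0.3
    n_low: int = 12
    n_high: int = 122
    bias_strength: float = 0.0
    seed: int = 0
    test_label: str = "test"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must be in (0, 1)")
        if self.n_low < 4:
            raise ValidationError("n_low must be >= 4")
        if self.n_high < self.n_low:
            raise ValidationError("n_high must be >= n_low")
        if self.tau_sens < 0 or self.tau_spec < 0:
            raise ValidationError("between-study SDs must be >= 0")
        if not -1 <= self.rho_threshold <= 1:
            raise ValidationError("rho_threshold must be in [-1, 1]")


def _draw_sizes(config: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-study total sizes and diseased counts (diseased re-drawn if 0)."""
    n = rng.integers(config.n_low, config.n_high + 1, size=config.k)
    d = np.empty(config.k, dtype=int)
    for i in range(config.k):
        di = rng.binomial(n[i], config.prevalence)
        while di == 0 or di == n[i]:
            di = rng.binomial(n[i], config.prevalence)
        d[i] = di
    return n, d


def _draw_accuracy(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-study (logit sens, logit fpr) from the between-study distribution."""
    mu_fpr = -config.mu_spec  # logit(1 - spec) = -logit(spec)
    cov = np.array(
        [
            [config.tau_sens**2, config.rho_threshold * config.tau_sens * config.tau_spec],
            [config.rho_threshold * config.tau_sens * config.tau_spec, config.tau_spec**2],
        ]
    )
    # svd factorization tolerates tau = 0 (singular covariance)
    draws = rng.multivariate_normal([config.mu_sens, mu_fpr], cov, size=config.k, method="svd")
    return draws[:, 0], draws[:, 1]


def _fill_cells(
    config: SynthConfig,
    n: np.ndarray,
    d: np.ndarray,
    logit_sens: np.ndarray,
    logit_fpr: np.ndarray,
    rng: np.random.Generator,
) -> list[StudyRecord]:
    records = []
    for i in range(config.k):
        ls, lf = logit_sens[i], logit_fpr[i]
        if config.bias_strength != 0.0:
            # Small-study effect: shift ln DOR = logit(sens) - logit(fpr),
            # split evenly between the two margins.
            shift = config.bias_strength / math.sqrt(
                effective_sample_size(int(d[i]), int(n[i] - d[i]))
            )
            ls += shift / 2.0
            lf -= shift / 2.0
        sens = inv_logit(ls)
        spec = 1.0 - inv_logit(lf)
        tp = int(rng.binomial(d[i], sens))
        tn = int(rng.binomial(n[i] - d[i], spec))
        records.append(
            StudyRecord(
                study_id=f"synth_{i + 1:03d}",
                test_label=config.test_label,
                tp=tp,
                fn=int(d[i]) - tp,
                tn=tn,
                fp=int(n[i] - d[i]) - tn,
            )
        )
    return records


def generate_panel(config: SynthConfig) -> list[StudyRecord]:
    """Generate one synthetic meta-analysis panel (one test arm)."""
    ss = np.random.SeedSequence(config.seed)
    rng_sizes, rng_acc, rng_cells = (np.random.default_rng(c) for c in ss.spawn(3))
    n, d = _draw_sizes(config, rng_sizes)
    ls, lf = _draw_accuracy(config, rng_acc)
    return _fill_cells(config, n, d, ls, lf, rng_cells)


def generate_paired_panel(
    config_test1: SynthConfig,
    config_test2: SynthConfig,
    shared_seed: int,
) -> list[StudyRecord]:
    """Generate a paired two-arm panel (both arms test the same patients).

    The two arms share each study's size and diseased count (drawn from
    ``shared_seed``) and differ only in their accuracy parameters and labels.
    """
    if config_test1.k != config_test2.k:
        raise ValidationError("paired arms must have the same number of studies")
    if config_test1.test_label == config_test2.test_label:
        raise ValidationError("paired arms need distinct test labels")
    ss = np.random.SeedSequence(shared_seed)
    shared_children = ss.spawn(3)
    rng_sizes = np.random.default_rng(shared_children[0])
    # Shared patient structure; sizes validated against the wider bounds.
    size_cfg = config_test1 if config_test1.n_high >= config_test2.n_high else config_test2
    n, d = _draw_sizes(size_cfg, rng_sizes)

    records: list[StudyRecord] = []
    for arm_idx, cfg in enumerate((config_test1, config_test2)):
        arm_ss = np.random.SeedSequence(entropy=shared_seed, spawn_key=(100 + arm_idx, cfg.seed))
        rng_acc, rng_cells = (np.random.default_rng(c) for c in arm_ss.spawn(2))
        ls, lf = _draw_accuracy(cfg, rng_acc)
        records.extend(_fill_cells(cfg, n, d, ls, lf, rng_cells))
    return records
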