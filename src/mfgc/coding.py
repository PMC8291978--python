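"""Population-coding statistics and the perceptron learning-speed readout.

Population sparseness is the Treves-Rolls statistic per pattern,

    S = (N - (sum_i x_i)^2 / sum_i x_i^2) / (N - 1),

averaged over patterns (1 = one active unit, 0 = uniform activity).  Total
variance, sum_i var(v_i) over units of the across-pattern spike-count
variance, measures the size of the occupied coding space; population
correlation is the mean pairwise between-unit correlation derived from the
covariance matrix.  GC-level statistics are normalized to the same
statistic computed on the MF input patterns.

Learning speed is read out by training a single-layer perceptron (10
logistic output units, delta rule) to classify the patterns into 10 random
balanced classes, and taking the inverse of the number of epochs needed to
reach a root-mean-square output error of 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import (CONTROL_SCALING, KO_SCALING, NetworkGeometry,
                      PatternParams, ResponseMatrix, build_geometry,
                      generate_mf_patterns, simulate_network_responses)

__all__ = [
    "PerceptronConfig",
    "PerceptronResult",
    "population_sparseness",
    "total_variance",
    "population_correlation",
    "train_perceptron",
    "learning_speed",
    "metric_grid",
]


@dataclass(frozen=True)
class PerceptronConfig:
    n_classes: int = 10
    learning_rate: float = 0.3
    max_epochs: int = 5000
    rms_criterion: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.rms_criterion < 1.0):
            raise ValueError("rms_criterion must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class PerceptronResult:
    epochs_to_criterion: int | None
    error_history: np.ndarray

    @property
    def reached(self) -> bool:
        return self.epochs_to_criterion is not None


def population_sparseness(responses: ResponseMatrix) -> float:
    """Mean Treves-Rolls population sparseness across activity patterns.

    All-zero patterns are undefined under the statistic and are skipped; if
    every pattern is silent the result is undefined (NaN).
    """
    x = responses.counts.astype(float)
    N = x.shape[1]
    sums = x.sum(axis=1)
    sq = (x ** 2).sum(axis=1)
    valid = sq > 0
    if not np.any(valid):
        return float("nan")
    s = (N - sums[valid] ** 2 / sq[valid]) / (N - 1)
    return float(np.mean(s))


def total_variance(responses: ResponseMatrix, ddof: int = 0) -> float:
    """Sum over units of the across-pattern spike-count variance.

    Population variance (ddof = 0) by default; switchable to the sample
    convention via ddof = 1.  Undefined (NaN) for a single pattern.
    """
    x = responses.counts.astype(float)
    if x.shape[0] < 2:
        return float("nan")
    return float(np.sum(np.var(x, axis=0, ddof=ddof)))


def population_correlation(responses: ResponseMatrix) -> float:
    """Mean pairwise between-unit correlation (off-diagonal mean).

    Units with zero across-pattern variance carry no signal and are
    excluded; NaN if fewer than two units remain.
    """
    x = responses.counts.astype(float)
    keep = np.var(x, axis=0) > 0
    if keep.sum() < 2:
        return float("nan")
    r = np.corrcoef(x[:, keep], rowvar=False)
    off = r[~np.eye(r.shape[0], dtype=bool)]
    return float(np.mean(off))


def _balanced_labels(n_patterns: int, n_classes: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Exactly balanced random class assignment (remainder spread randomly)."""
    base = np.arange(n_patterns) % n_classes
    return rng.permutation(base)


def train_perceptron(patterns: ResponseMatrix,
                     cfg: PerceptronConfig = PerceptronConfig(),
                     labels: np.ndarray | None = None,
                     input_scaling: str = "center") -> PerceptronResult:
    """Train a one-layer perceptron to classify patterns into random classes.

    Inputs are the spike counts, mean-centered per unit ("center", the
    default) plus a bias; outputs are logistic units with one-hot 0/1
    targets, trained by full-batch delta rule (gradient of the summed
    squared error, averaged over patterns).  Centering removes the common
    positive offset that destabilizes gradient descent, but deliberately
    keeps each unit's response *variance*: the signal magnitude of a
    population is part of what distinguishes conditions, and full
    per-unit standardization ("standardize") would cancel it.  "raw" uses
    the counts untouched.  Training stops when the RMS output error drops
    to the criterion; not reaching it within max_epochs is a valid
    outcome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x70657263]))
    x = patterns.counts.astype(float)
    n_pat, n_units = x.shape
    if input_scaling == "standardize":
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    elif input_scaling == "center":
        x = x - x.mean(axis=0)
    elif input_scaling != "raw":
        raise ValueError("input_scaling must be raw, center or standardize")
    X = np.hstack([x, np.ones((n_pat, 1))])

    if labels is None:
        labels = _balanced_labels(n_pat, cfg.n_classes, rng)
    T = np.zeros((n_pat, cfg.n_classes))
    T[np.arange(n_pat), labels] = 1.0

    W = rng.normal(0.0, 0.01, size=(n_units + 1, cfg.n_classes))
    history = np.empty(cfg.max_epochs)
    epochs = None
    for epoch in range(cfg.max_epochs):
        Y = 1.0 / (1.0 + np.exp(-X @ W))
        err = T - Y
        rms = float(np.sqrt(np.mean(err ** 2)))
        history[epoch] = rms
        if rms <= cfg.rms_criterion:
            epochs = epoch + 1
            break
        grad = X.T @ (err * Y * (1.0 - Y)) / n_pat
        W += cfg.learning_rate * grad
    n_done = epoch + 1
    return PerceptronResult(epochs, history[:n_done])


def learning_speed(result: PerceptronResult) -> float:
    """Inverse of the epochs needed to reach criterion; 0 if never reached."""
    if not result.reached:
        return 0.0
    return 1.0 / result.epochs_to_criterion


@dataclass
class GridPointResult:
    fraction_active: float
    correlation_radius: float
    condition: str
    seed: int
    sparseness_mf: float
    sparseness_gc: float
    total_variance_mf: float
    total_variance_gc: float
    correlation_gc: float
    learning_speed_mf: float
    learning_speed_gc: float
    active_gc_fraction: float

    @property
    def normalized_sparseness(self) -> float:
        return self.sparseness_gc / self.sparseness_mf

    @property
    def normalized_total_variance(self) -> float:
        return self.total_variance_gc / self.total_variance_mf

    @property
    def normalized_learning_speed(self) -> float:
        if self.learning_speed_mf == 0:
            return float("nan")
        return self.learning_speed_gc / self.learning_speed_mf


def metric_grid(f_values, sigma_values, conditions: dict,
                gc_model, synapses, seed: int = 0,
                n_patterns: int = 640,
                perceptron_cfg: PerceptronConfig | None = None,
                geometry: NetworkGeometry | None = None) -> pd.DataFrame:
    """Run the full pattern -> response -> coding pipeline over a (f, sigma) grid.

    ``conditions`` maps a label to a ConditionScaling (e.g. control / KO).
    Returns a tidy table with one row per (f, sigma, condition) carrying the
    MF- and GC-level statistics and the MF-normalized ratios; the per-sigma
    median across f (the summary used for the correlation-radius profiles)
    can be obtained with ``df.groupby(["condition", "sigma"]).median()``.
    """
    from .network import active_fraction

    if geometry is None:
        geometry = build_geometry(seed)
    rows = []
    for sigma in sigma_values:
        for f in f_values:
            pat_params = PatternParams(fraction_active=f,
                                       correlation_radius=sigma,
                                       n_patterns=n_patterns, seed=seed)
            mf = generate_mf_patterns(geometry, pat_params)
            pcfg = perceptron_cfg or PerceptronConfig(seed=seed)
            mf_result = train_perceptron(mf, pcfg)
            ls_mf = learning_speed(mf_result)
            s_mf = population_sparseness(mf)
            tv_mf = total_variance(mf)
            for label, scaling in conditions.items():
                gc = simulate_network_responses(geometry, mf, gc_model,
                                                synapses, scaling,
                                                condition=label)
                gc_result = train_perceptron(gc, pcfg)
                row = GridPointResult(
                    fraction_active=f, correlation_radius=sigma,
                    condition=label, seed=seed,
                    sparseness_mf=s_mf,
                    sparseness_gc=population_sparseness(gc),
                    total_variance_mf=tv_mf,
                    total_variance_gc=total_variance(gc),
                    correlation_gc=population_correlation(gc),
                    learning_speed_mf=ls_mf,
                    learning_speed_gc=learning_speed(gc_result),
                    active_gc_fraction=active_fraction(gc),
                )
                rows.append({
                    "f": f, "sigma": sigma, "condition": label, "seed": seed,
                    "sparseness_mf": row.sparseness_mf,
                    "sparseness_gc": row.sparseness_gc,
                    "normalized_sparseness": row.normalized_sparseness,
                    "total_variance_mf": row.total_variance_mf,
                    "total_variance_gc": row.total_variance_gc,
                    "normalized_total_variance": row.normalized_total_variance,
                    "correlation_gc": row.correlation_gc,
                    "learning_speed_mf": row.learning_speed_mf,
                    "learning_speed_gc": row.learning_speed_gc,
                    "normalized_learning_speed": row.normalized_learning_speed,
                    "active_gc_fraction": row.active_gc_fraction,
                })
    return pd.DataFrame(rows)
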