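"""Plasmid stability and conjugation metrics.

Loss rate per generation (L) is estimated from serial-passage retention
data under the geometric-decay model F(g) = F(0) * (1 - L)**g:

* ``log_linear`` (default): least-squares fit of ln F(g) against g over all
  checkpoints with non-zero retention; L = 1 - exp(slope). Uses every
  checkpoint, so it is robust to colony-sampling noise.
* ``endpoint``: geometric inversion between the first and last checkpoints
  with non-zero retention, L = 1 - (F_t / F_s)**(1 / (t - s)).

Both reduce to the same value on noiseless geometric decay. Uncertainty is
a parametric bootstrap of the binomial colony sampling (1000 replicates,
seeded), reported as a percentile confidence interval.

Conjugation frequency is transconjugants per donor cell, T/D after dilution
correction; when no transconjugant is detected the detection limit 1/D is
reported as an upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import MatingCounts, PassageSeries, ValidationError

__all__ = [
    "LossRateEstimate",
    "ConjugationFrequency",
    "EstimationError",
    "estimate_loss_rate",
    "conjugation_frequency",
    "fold_change",
    "aggregate_loss_rates",
]

_BOOTSTRAP_REPLICATES = 1000


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass(frozen=True)
class LossRateEstimate:
    """Per-generation plasmid loss rate with a bootstrap confidence interval."""

    rate_per_generation: float
    ci_low: float
    ci_high: float
    n_checkpoints: int
    method: str
    n_zero_dropped: int = 0
    is_lower_bound: bool = False


@dataclass(frozen=True)
class ConjugationFrequency:
    """Transconjugants per donor; an upper (detection-limit) bound when T = 0."""

    frequency: float
    is_upper_bound: bool
    transconjugants: float
    donors: float


def _fit_loss_rate(
    gens: np.ndarray, retentions: np.ndarray, method: str
) -> float:
    """Point estimate of L from one retention curve (informative points only)."""
    keep = retentions > 0
    g, f = gens[keep], retentions[keep]
    if method == "log_linear":
        # slope of ln F on g; intercept left free to absorb F(0) != 1
        x = g - g.mean()
        y = np.log(f)
        denom = float(x @ x)
        slope = float(x @ (y - y.mean())) / denom if denom > 0 else 0.0
        L = 1.0 - math.exp(slope)
    elif method == "endpoint":
        if g[-1] == g[0]:
            raise EstimationError("endpoint method needs two distinct generations")
        L = 1.0 - (f[-1] / f[0]) ** (1.0 / (g[-1] - g[0]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(max(L, 0.0), 1.0)


def estimate_loss_rate(
    series: PassageSeries,
    method: str = "log_linear",
    seed: int = 0,
    n_bootstrap: int = _BOOTSTRAP_REPLICATES,
) -> LossRateEstimate:
    """Estimate the per-generation loss rate L from a passage series.

    Checkpoints with zero retention are excluded from the fit (their log is
    undefined); the number dropped is recorded. If *every* checkpoint after
    generation zero shows zero retention, L cannot be estimated — only
    bounded below by the total loss implied before the first checkpoint —
    and the result is flagged as a lower bound.

    The confidence interval is a seeded parametric bootstrap: colony counts
    are redrawn as binomials around the fitted retention curve and the
    estimator reapplied (percentile 95% interval).
    """
    gens = series.generations
    rets = series.retentions
    tested = series.colonies_tested
    if len(gens) < 2:
        raise EstimationError("need at least two checkpoints to estimate a rate")
    if rets[0] <= 0:
        raise EstimationError("retention at the first checkpoint must be positive")
    informative = rets > 0
    n_dropped = int((~informative).sum())
    if informative.sum() < 2:
        # total loss before the first post-zero checkpoint: retention fell
        # below one detectable colony within that interval
        g1 = gens[1]
        bound = 1.0 - (1.0 / tested[1]) ** (1.0 / g1)
        return LossRateEstimate(
            rate_per_generation=bound,
            ci_low=bound,
            ci_high=1.0,
            n_checkpoints=len(gens),
            method=method,
            n_zero_dropped=n_dropped,
            is_lower_bound=True,
        )
    L = _fit_loss_rate(gens, rets, method)

    # parametric bootstrap around the fitted curve
    rng = np.random.default_rng(seed)
    f0 = rets[0]
    fitted = f0 * (1.0 - L) ** (gens - gens[0])
    draws = rng.binomial(
        tested[None, :].repeat(n_bootstrap, axis=0),
        np.clip(fitted, 0.0, 1.0)[None, :],
    )
    boot = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        f_i = draws[i] / tested
        if (f_i > 0).sum() < 2 or f_i[0] <= 0:
            boot[i] = 1.0
            continue
        boot[i] = _fit_loss_rate(gens, f_i, method)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    return LossRateEstimate(
        rate_per_generation=L,
        ci_low=float(min(ci_low, L)),
        ci_high=float(max(ci_high, L)),
        n_checkpoints=len(gens),
        method=method,
        n_zero_dropped=n_dropped,
    )


def conjugation_frequency(counts: MatingCounts) -> ConjugationFrequency:
    """Transconjugants per donor cell, dilution-corrected.

    With zero transconjugants the assay only establishes a detection limit:
    the frequency is reported as the upper bound 1/D and flagged.
    """
    D = counts.donors_corrected
    T = counts.transconjugants_corrected
    if T == 0:
        return ConjugationFrequency(
            frequency=1.0 / D, is_upper_bound=True, transconjugants=0.0, donors=D
        )
    return ConjugationFrequency(
        frequency=T / D, is_upper_bound=False, transconjugants=T, donors=D
    )


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    is_upper_bound: bool = False
    is_lower_bound: bool = False


def fold_change(a: ConjugationFrequency, b: ConjugationFrequency) -> FoldChange:
    """Ratio a/b of two conjugation frequencies with bound propagation.

    If the numerator is an upper bound the ratio is an upper bound; if the
    denominator is an upper bound the ratio is a lower bound (the true
    denominator can only be smaller).
    """
    if a.frequency == 0 and b.frequency == 0:
        raise EstimationError("fold change undefined: both frequencies are zero")
    if b.frequency == 0:
        raise EstimationError("fold change undefined: denominator is exactly zero")
    return FoldChange(
        ratio=a.frequency / b.frequency,
        is_upper_bound=a.is_upper_bound and not b.is_upper_bound,
        is_lower_bound=b.is_upper_bound and not a.is_upper_bound,
    )


def aggregate_loss_rates(
    estimates: Sequence[LossRateEstimate],
) -> tuple[float, float]:
    """Mean ± sd of loss rates across biological replicates.

    Mirrors the convention of reporting a standard deviation over repeated
    stability assays (ddof=1; sd is 0 for a single replicate).
    """
    if not estimates:
        raise ValidationError("no estimates to aggregate")
    rates = np.array([e.rate_per_generation for e in estimates])
    sd = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
    return float(rates.mean()), sd
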