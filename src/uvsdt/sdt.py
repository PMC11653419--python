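"""Unequal-variance logistic signal detection model.

Two logistic distributions over a bounded decision driver represent the
internal evidence of participants who did not (S1) and did (S2) experience a
clinically important improvement.  A yes-decision corresponds to the evidence
exceeding a criterion ``c``, so the hit rate is the S2 upper tail and the
false-alarm rate the S1 upper tail.  The module provides the distribution
functions, confusion probabilities, ROC and logit-ROC (zROC analogue)
analysis, likelihood-ratio functions and criterion solvers, including the
expected-value-optimal likelihood-ratio threshold

    beta = [P(T-)/P(T+)] * [B(T-&D-) + C(T-&D+)] / [B(T+&D+) + C(T+&D-)].

Parameterization: each component has location ``mu`` and scale ``s`` (both in
driver units), equivalently intercept ``theta1 = -mu/s`` and slope
``theta2 = 1/s`` of the logistic regression ``logit P(yes|x) = theta1 +
theta2*x``.  For logistic SDT the ROC is exactly linear in logit-logit
coordinates with slope ``s1/s2`` and intercept ``(mu2 - mu1)/s2``; the
intercept generalizes the equal-variance accuracy index ``2*mu/s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, log_expit, logit as _logit

__all__ = [
    "LogisticComponent",
    "SdtModel",
    "ConfusionProbabilities",
    "RocCurve",
    "LogitRoc",
    "UtilityContext",
    "CriterionRoot",
    "CriterionResult",
    "cdf",
    "pdf",
    "confusion_at_criterion",
    "roc_curve",
    "auc",
    "logit_roc",
    "likelihood_ratio",
    "log_likelihood_ratio",
    "unbiased_criterion",
    "criterion_for_beta",
    "lr_extremum",
    "optimal_beta",
    "reverse_model",
    "map_criterion_back",
]


@dataclass(frozen=True)
class LogisticComponent:
    """Logistic distribution with location ``mu`` and scale ``s`` (driver units)."""

    mu: float
    s: float

    def __post_init__(self) -> None:
        if not (self.s > 0 and math.isfinite(self.s)):
            raise ValueError(f"scale must be positive and finite, got s={self.s}")
        if not math.isfinite(self.mu):
            raise ValueError(f"location must be finite, got mu={self.mu}")

    @property
    def theta1(self) -> float:
        """Logistic-regression intercept, -mu/s (dimensionless)."""
        return -self.mu / self.s

    @property
    def theta2(self) -> float:
        """Logistic-regression slope, 1/s (per driver unit)."""
        return 1.0 / self.s

    @classmethod
    def from_theta(cls, theta1: float, theta2: float) -> "LogisticComponent":
        if not theta2 > 0:
            raise ValueError(f"slope theta2 must be positive, got {theta2}")
        return cls(mu=-theta1 / theta2, s=1.0 / theta2)


@dataclass(frozen=True)
class SdtModel:
    """Pair of logistic components over a bounded driver range.

    ``s1`` is the population without a clinically important improvement,
    ``s2`` the population with one.  ``orientation``/``reversal_offset``
    record whether the driver was reversed (x -> offset - x) before fitting.
    """

    s1: LogisticComponent
    s2: LogisticComponent
    x_min: float
    x_max: float
    orientation: str = "as_is"
    reversal_offset: float | None = None

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError(f"need x_min < x_max, got [{self.x_min}, {self.x_max}]")
        if self.orientation not in ("as_is", "reversed"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.orientation == "reversed" and self.reversal_offset is None:
            raise ValueError("reversed model must record its reversal_offset")


@dataclass(frozen=True)
class ConfusionProbabilities:
    tp: float
    fp: float
    tn: float
    fn: float


@dataclass(frozen=True)
class RocCurve:
    """ROC points swept over a uniform criterion grid, sorted by increasing fp."""

    criterion: np.ndarray
    fp: np.ndarray
    tp: np.ndarray


@dataclass(frozen=True)
class LogitRoc:
    """Analytic and empirically refit logit-ROC line.

    ``intercept`` is the accuracy index: it reduces to 2*mu/s for an
    equal-variance model with symmetric modes at -mu and +mu.
    """

    slope: float
    intercept: float
    slope_empirical: float
    intercept_empirical: float


@dataclass(frozen=True)
class UtilityContext:
    """Base rates and payoff terms of the optimal-criterion equation.

    Benefits attach to agreeing truth/decision states, costs to disagreeing
    ones; all four share one arbitrary utility unit.
    """

    p_t_plus: float
    p_t_minus: float
    b_pp: float  # B(T+ & D+)
    b_nn: float  # B(T- & D-)
    c_pn: float  # C(T+ & D-)
    c_np: float  # C(T- & D+)

    def __post_init__(self) -> None:
        if not (self.p_t_plus > 0 and self.p_t_minus > 0):
            raise ValueError("base rates must both be positive")
        if abs(self.p_t_plus + self.p_t_minus - 1.0) > 1e-9:
            raise ValueError("base rates must sum to 1")


@dataclass(frozen=True)
class CriterionRoot:
    """A driver value where LR(x) crosses the target ratio beta.

    ``class_below``/``class_above`` label the adjacent regions as lenient
    (LR < 1) or strict (LR > 1).
    """

    x: float
    lr: float
    class_below: str
    class_above: str


@dataclass(frozen=True)
class CriterionResult:
    beta: float
    roots: tuple[CriterionRoot, ...]
    always: str | None = None  # "strict"/"lenient" when LR never crosses beta

    def values(self) -> list[float]:
        return [r.x for r in self.roots]


# ---------------------------------------------------------------------------
# distribution functions


def cdf(component: LogisticComponent, x) -> np.ndarray | float:
    """Logistic CDF 1/(1 + exp(-(x - mu)/s)), overflow-safe."""
    z = (np.asarray(x, dtype=float) - component.mu) / component.s
    out = expit(z)
    return float(out) if out.ndim == 0 else out


def pdf(component: LogisticComponent, x) -> np.ndarray | float:
    """Logistic density; peak value is 1/(4 s) at x = mu."""
    out = np.exp(log_pdf(component, x))
    return float(out) if np.ndim(out) == 0 else out


def log_pdf(component: LogisticComponent, x) -> np.ndarray | float:
    # log f = -|z| - 2 log(1 + exp(-|z|)) - log s  (symmetric in z)
    z = np.abs((np.asarray(x, dtype=float) - component.mu) / component.s)
    out = -z + 2.0 * log_expit(z) - np.log(component.s)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# confusion probabilities and ROC


def confusion_at_criterion(model: SdtModel, c: float) -> ConfusionProbabilities:
    """Confusion probabilities for a yes-decision when evidence exceeds ``c``.

    tp + fn = 1 and fp + tn = 1 by construction (each pair is the two tails
    of one distribution).
    """
    fn = cdf(model.s2, c)
    tn = cdf(model.s1, c)
    return ConfusionProbabilities(tp=1.0 - fn, fp=1.0 - tn, tn=tn, fn=fn)


def roc_curve(model: SdtModel, n_grid: int = 512) -> RocCurve:
    """Sweep the criterion over [x_min, x_max] on a uniform grid.

    With a bounded driver range the endpoints are interior to the unit
    square; the curve does not reach (0,0) or (1,1).
    """
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    c = np.linspace(model.x_min, model.x_max, n_grid)
    fp = 1.0 - cdf(model.s1, c)
    tp = 1.0 - cdf(model.s2, c)
    order = np.argsort(fp, kind="stable")
    return RocCurve(criterion=c[order], fp=fp[order], tp=tp[order])


def auc(roc: RocCurve, mode: str = "partial") -> float:
    """Trapezoidal area under the ROC.

    ``partial`` (default) integrates only over the observed fp-span — for a
    bounded driver range this can fall well below 0.5 even for
    better-than-chance models.  ``closed`` appends straight chords to (0,0)
    and (1,1) before integrating.
    """
    if len(roc.fp) < 2:
        raise ValueError("ROC needs at least 2 points")
    fp, tp = roc.fp, roc.tp
    if mode == "closed":
        fp = np.concatenate(([0.0], fp, [1.0]))
        tp = np.concatenate(([0.0], tp, [1.0]))
    elif mode != "partial":
        raise ValueError(f"unknown AUC mode {mode!r}")
    return float(np.trapezoid(tp, fp))


def logit_roc(model: SdtModel, n_grid: int = 512) -> LogitRoc:
    """Logit-logit ROC line: analytic (s1/s2, (mu2-mu1)/s2) plus a
    least-squares refit through logit-transformed ROC points.

    From logit(tp) = (mu2 - c)/s2 and logit(fp) = (mu1 - c)/s1 the curve is
    exactly linear, so the two must agree to numerical precision.
    """
    slope = model.s1.s / model.s2.s
    intercept = (model.s2.mu - model.s1.mu) / model.s2.s
    roc = roc_curve(model, n_grid=n_grid)
    lx = _logit(roc.fp)
    ly = _logit(roc.tp)
    ok = np.isfinite(lx) & np.isfinite(ly)
    coeffs = np.polynomial.polynomial.polyfit(lx[ok], ly[ok], 1)
    return LogitRoc(
        slope=slope,
        intercept=intercept,
        slope_empirical=float(coeffs[1]),
        intercept_empirical=float(coeffs[0]),
    )


# ---------------------------------------------------------------------------
# likelihood ratio and criteria


def log_likelihood_ratio(model: SdtModel, x) -> np.ndarray | float:
    return log_pdf(model.s2, x) - log_pdf(model.s1, x)


def likelihood_ratio(model: SdtModel, x) -> np.ndarray | float:
    """LR(x) = pdf_S2(x) / pdf_S1(x), evaluated in log space."""
    out = np.exp(log_likelihood_ratio(model, x))
    return float(out) if np.ndim(out) == 0 else out


def _classify(lr_value: float) -> str:
    return "lenient" if lr_value < 1.0 else "strict"


def criterion_for_beta(
    model: SdtModel,
    beta: float,
    n_grid: int = 4096,
    xtol: float = 1e-12,
) -> CriterionResult:
    """All in-range roots of LR(x) = beta, by sign-change bracketing on a
    dense grid followed by bracketed root refinement.

    Each root is annotated with the lenient/strict class of the flanking
    regions (lenient <=> LR < 1).  If no root exists the result carries an
    ``always`` flag when LR stays on one side of 1 over the whole range.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    grid = np.linspace(model.x_min, model.x_max, n_grid)
    g = np.asarray(log_likelihood_ratio(model, grid)) - math.log(beta)

    roots: list[CriterionRoot] = []
    fun = lambda x: float(log_likelihood_ratio(model, x)) - math.log(beta)
    tol_dup = 1e-9 * (model.x_max - model.x_min)
    for i in np.nonzero(np.diff(np.sign(g)) != 0)[0]:
        lo, hi = grid[i], grid[i + 1]
        r = lo if g[i] == 0.0 else (hi if g[i + 1] == 0.0 else brentq(fun, lo, hi, xtol=xtol))
        if roots and abs(r - roots[-1].x) <= tol_dup:
            continue
        h = max(1e-6 * (model.x_max - model.x_min), 1e-9)
        roots.append(
            CriterionRoot(
                x=float(r),
                lr=float(likelihood_ratio(model, r)),
                class_below=_classify(float(likelihood_ratio(model, max(r - h, model.x_min)))),
                class_above=_classify(float(likelihood_ratio(model, min(r + h, model.x_max)))),
            )
        )

    always = None
    if not roots:
        lr_grid = np.exp(g) * beta
        if np.all(lr_grid > 1.0):
            always = "strict"
        elif np.all(lr_grid < 1.0):
            always = "lenient"
    return CriterionResult(beta=float(beta), roots=tuple(roots), always=always)


def unbiased_criterion(model: SdtModel, n_grid: int = 4096) -> CriterionResult:
    """Driver value(s) where the likelihood ratio equals 1.

    An empty root list with ``always='strict'`` reproduces the situation
    where the criterion lies outside the driver range and every in-range
    decision is strict (and symmetrically for lenient).
    """
    return criterion_for_beta(model, 1.0, n_grid=n_grid)


def _dlog_lr(model: SdtModel, x) -> np.ndarray:
    """Derivative of log LR; d log f/dx = (1 - 2 F(z))/s for a logistic."""
    x = np.asarray(x, dtype=float)
    z1 = (x - model.s1.mu) / model.s1.s
    z2 = (x - model.s2.mu) / model.s2.s
    return (1.0 - 2.0 * expit(z2)) / model.s2.s - (1.0 - 2.0 * expit(z1)) / model.s1.s


def lr_extremum(
    model: SdtModel, n_grid: int = 4096, xtol: float = 1e-10
) -> tuple[float, float, str] | None:
    """Interior stationary point of log LR, or None if log LR is monotone.

    Returns (x*, LR(x*), kind) with kind 'maximum' or 'minimum'.  With equal
    scales log LR is strictly monotone (not linear, but one-signed slope),
    so there is no interior extremum; s2 < s1 yields an interior maximum and
    s2 > s1 an interior minimum, by the tail slopes +-(1/s1 - 1/s2).
    """
    grid = np.linspace(model.x_min, model.x_max, n_grid)
    d = _dlog_lr(model, grid)
    idx = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    if d[i] == 0.0:
        x_star = float(grid[i])
    elif d[i + 1] == 0.0:
        x_star = float(grid[i + 1])
    else:
        x_star = float(brentq(lambda x: float(_dlog_lr(model, np.array([x]))[0]),
                              grid[i], grid[i + 1], xtol=xtol))
    kind = "maximum" if d[i] > 0 else "minimum"
    return x_star, float(likelihood_ratio(model, x_star)), kind


def optimal_beta(context: UtilityContext) -> float:
    """Likelihood-ratio threshold that maximizes expected value.

    beta = [P(T-)/P(T+)] * [B(T-&D-) + C(T-&D+)] / [B(T+&D+) + C(T+&D-)].
    Equal base rates with all-equal benefits and costs give beta = 1 (the
    unbiased criterion), and beta is invariant under a common rescaling of
    all four utility terms.
    """
    denom = context.b_pp + context.c_pn
    if denom == 0:
        raise ZeroDivisionError("B(T+&D+) + C(T+&D-) must be non-zero")
    return (context.p_t_minus / context.p_t_plus) * (context.b_nn + context.c_np) / denom


# ---------------------------------------------------------------------------
# driver reversal


def reverse_model(model: SdtModel, offset: float | None = None) -> SdtModel:
    """Model for the reversed driver x' = offset - x.

    A logistic(mu, s) variable maps to logistic(offset - mu, s), and the
    driver range maps to [offset - x_max, offset - x_min].  Applying the
    reversal twice with the same offset restores the original model.
    """
    if offset is None:
        if model.reversal_offset is None:
            raise ValueError("offset required when the model records none")
        offset = model.reversal_offset
    flipped = "reversed" if model.orientation == "as_is" else "as_is"
    return SdtModel(
        s1=replace(model.s1, mu=offset - model.s1.mu),
        s2=replace(model.s2, mu=offset - model.s2.mu),
        x_min=offset - model.x_max,
        x_max=offset - model.x_min,
        orientation=flipped,
        reversal_offset=offset if flipped == "reversed" else None,
    )


def map_criterion_back(model: SdtModel, c: float) -> float:
    """Express a criterion found on a reversed driver scale in original units."""
    if model.orientation == "reversed":
        assert model.reversal_offset is not None
        return model.reversal_offset - c
    return c
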