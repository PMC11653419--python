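"""Bayesian logistic regression per outcome population, and model assembly.

For each population (S1 = no clinically important improvement, S2 =
improvement) the probability of a yes-decision follows

    P(y = 1 | x) = expit(theta1 + theta2 * x),

which is the logistic CDF with location mu = -theta1/theta2 and scale
s = 1/theta2.  The posterior over (theta1, theta2) under a vague independent
normal prior is explored with an adaptive random-walk Metropolis sampler
(default 20,000 draws after 5,000 burn-in, proposal preconditioned on the
curvature at the posterior mode); a deterministic dense-grid integration is
available as a cross-checking fallback for this 2-parameter posterior.

The one-sided slope test asks whether the data are consistent with the
driver assumption at all: H0 theta2 = 0 against H1 theta2 > 0, rejected when
the posterior mass P(theta2 > 0) reaches 1 - alpha (default alpha = 0.01).
Drivers whose pooled response probability falls with x are reversed first
(x -> offset - x) so the slope direction convention holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .cohort import DecisionDataset
from .sdt import LogisticComponent, SdtModel

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "PosteriorFit",
    "SeparationError",
    "fit_population",
    "slope_test",
    "orient_driver",
    "reverse_dataset",
    "build_sdt_model",
]


@dataclass(frozen=True)
class PriorConfig:
    """Independent zero-centred normal priors on theta1 and theta2.

    Defaults are vague relative to any plausible driver scale: sd 20 on the
    (dimensionless) intercept and sd 20 on the slope, whose realistic
    magnitude is well below 1 per driver unit.
    """

    sd_theta1: float = 20.0
    sd_theta2: float = 20.0

    def describe(self) -> str:
        return f"theta1 ~ N(0, {self.sd_theta1}^2), theta2 ~ N(0, {self.sd_theta2}^2)"


@dataclass(frozen=True)
class SamplerConfig:
    draws: int = 20_000
    burn_in: int = 5_000
    thin: int = 1
    target_acceptance: float = 0.3
    adapt_interval: int = 200


@dataclass
class PosteriorFit:
    population: str
    theta1_hat: float  # posterior mode
    theta2_hat: float
    theta1_mle: float
    theta2_mle: float
    bci_theta1: tuple[float, float]
    bci_theta2: tuple[float, float]
    p_slope_positive: float
    seed: int
    prior: PriorConfig
    method: str
    diagnostics: dict = field(default_factory=dict)
    samples: np.ndarray | None = None


class SeparationError(RuntimeError):
    """The two response classes are perfectly separated along the driver."""


# ---------------------------------------------------------------------------
# likelihood / posterior machinery


def _check_inputs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.ndim != 1 or y.shape != x.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("driver values must be finite")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("responses must be binary 0/1")
    return x, y.astype(float)


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    if y.min() == y.max():
        return True
    x1, x0 = x[y == 1], x[y == 0]
    return bool(x1.min() > x0.max() or x1.max() < x0.min())


def _log_posterior(theta: np.ndarray, x: np.ndarray, y: np.ndarray, prior: PriorConfig) -> float:
    eta = theta[0] + theta[1] * x
    ll = float(np.sum(y * log_expit(eta) + (1.0 - y) * log_expit(-eta)))
    lp = -0.5 * (theta[0] / prior.sd_theta1) ** 2 - 0.5 * (theta[1] / prior.sd_theta2) ** 2
    return ll + lp


def _neg_log_posterior_grad(theta, x, y, prior):
    eta = theta[0] + theta[1] * x
    p = expit(eta)
    resid = y - p
    g = np.array(
        [
            -np.sum(resid) + theta[0] / prior.sd_theta1**2,
            -np.sum(resid * x) + theta[1] / prior.sd_theta2**2,
        ]
    )
    return g


def _posterior_mode(x, y, prior) -> tuple[np.ndarray, np.ndarray]:
    """MAP estimate and inverse curvature (covariance proxy) at the mode."""
    res = minimize(
        lambda t: -_log_posterior(t, x, y, prior),
        x0=np.zeros(2),
        jac=lambda t: _neg_log_posterior_grad(t, x, y, prior),
        method="BFGS",
    )
    theta = res.x
    p = expit(theta[0] + theta[1] * x)
    w = p * (1.0 - p)
    hess = np.array(
        [
            [np.sum(w) + 1.0 / prior.sd_theta1**2, np.sum(w * x)],
            [np.sum(w * x), np.sum(w * x * x) + 1.0 / prior.sd_theta2**2],
        ]
    )
    return theta, np.linalg.inv(hess)


def _mle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood estimates via statsmodels Logit."""
    import statsmodels.api as sm

    design = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, design).fit(disp=0)
    return float(res.params[0]), float(res.params[1])


def _metropolis(x, y, prior, sampler, seed, start, prop_cov):
    # log posterior in sufficient-statistic form:
    #   theta1*sum(y) + theta2*sum(x*y) + sum(log_expit(-eta)) + log prior
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(prop_cov + 1e-12 * np.eye(2))
    scale = 2.4 / math.sqrt(2.0)
    s_y = float(np.sum(y))
    s_xy = float(np.sum(x * y))
    v1 = prior.sd_theta1**2
    v2 = prior.sd_theta2**2

    def lp_fun(t1: float, t2: float) -> float:
        tail = float(np.sum(log_expit(-(t1 + t2 * x))))
        return t1 * s_y + t2 * s_xy + tail - 0.5 * (t1 * t1 / v1 + t2 * t2 / v2)

    t1, t2 = float(start[0]), float(start[1])
    lp = lp_fun(t1, t2)
    total = sampler.burn_in + sampler.draws * sampler.thin
    steps = rng.standard_normal((total, 2)) @ chol.T
    log_u = np.log(rng.random(total))
    kept = np.empty((sampler.draws, 2))
    accepted = 0
    window_accepted = 0
    k = 0
    for i in range(total):
        p1 = t1 + scale * steps[i, 0]
        p2 = t2 + scale * steps[i, 1]
        lp_prop = lp_fun(p1, p2)
        if log_u[i] < lp_prop - lp:
            t1, t2, lp = p1, p2, lp_prop
            accepted += 1
            window_accepted += 1
        if i < sampler.burn_in:
            if (i + 1) % sampler.adapt_interval == 0:
                rate = window_accepted / sampler.adapt_interval
                scale *= math.exp(rate - sampler.target_acceptance)
                window_accepted = 0
        else:
            j = i - sampler.burn_in
            if j % sampler.thin == 0:
                kept[k, 0] = t1
                kept[k, 1] = t2
                k += 1
    return kept[:k], accepted / total


def fit_population(
    x,
    y,
    *,
    population: str = "S1",
    prior: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
    method: str = "metropolis",
    grid_points: int = 241,
    grid_halfwidth: float = 8.0,
    allow_separation: bool = False,
) -> PosteriorFit:
    """Posterior over (theta1, theta2) for one population's yes/no responses.

    Returns point estimates (posterior mode and MLE), central 95% credible
    intervals, and P(theta2 > 0).  Deterministic given ``seed``; the
    ``grid`` method is deterministic outright.
    """
    x, y = _check_inputs(x, y)
    prior = prior or PriorConfig()
    sampler = sampler or SamplerConfig()
    if np.ptp(x) == 0:
        raise ValueError("driver column is constant; slope is unidentifiable")
    if _is_separated(x, y) and not allow_separation:
        raise SeparationError(
            "response classes are perfectly separated along the driver; the "
            "likelihood is degenerate (pass allow_separation=True to fit under "
            "the proper prior anyway)"
        )

    mode, cov = _posterior_mode(x, y, prior)
    try:
        theta1_mle, theta2_mle = _mle(x, y)
    except Exception:  # separation override: MLE diverges, report MAP instead
        theta1_mle, theta2_mle = float(mode[0]), float(mode[1])

    if method == "metropolis":
        samples, acc = _metropolis(x, y, prior, sampler, seed, mode, cov)
        bci1 = tuple(np.percentile(samples[:, 0], [2.5, 97.5]))
        bci2 = tuple(np.percentile(samples[:, 1], [2.5, 97.5]))
        p_pos = float(np.mean(samples[:, 1] > 0))
        diagnostics = {"acceptance_rate": acc, "n_samples": len(samples)}
    elif method == "grid":
        se = np.sqrt(np.diag(cov))
        g1 = np.linspace(mode[0] - grid_halfwidth * se[0], mode[0] + grid_halfwidth * se[0], grid_points)
        g2 = np.linspace(mode[1] - grid_halfwidth * se[1], mode[1] + grid_halfwidth * se[1], grid_points)
        logp = np.empty((grid_points, grid_points))
        for i, t1 in enumerate(g1):
            eta = t1 + np.outer(g2, x)
            ll = np.sum(y * log_expit(eta) + (1.0 - y) * log_expit(-eta), axis=1)
            logp[i] = ll - 0.5 * (t1 / prior.sd_theta1) ** 2 - 0.5 * (g2 / prior.sd_theta2) ** 2
        post = np.exp(logp - logp.max())
        post /= post.sum()
        m1 = post.sum(axis=1)  # marginal over theta1 grid
        m2 = post.sum(axis=0)
        bci1 = _grid_interval(g1, m1)
        bci2 = _grid_interval(g2, m2)
        p_pos = float(m2[g2 > 0].sum() + (0.5 * m2[g2 == 0].sum() if np.any(g2 == 0) else 0.0))
        samples = None
        diagnostics = {"grid_points": grid_points, "grid_halfwidth": grid_halfwidth}
    else:
        raise ValueError(f"unknown method {method!r}")

    return PosteriorFit(
        population=population,
        theta1_hat=float(mode[0]),
        theta2_hat=float(mode[1]),
        theta1_mle=theta1_mle,
        theta2_mle=theta2_mle,
        bci_theta1=(float(bci1[0]), float(bci1[1])),
        bci_theta2=(float(bci2[0]), float(bci2[1])),
        p_slope_positive=p_pos,
        seed=seed,
        prior=prior,
        method=method,
        diagnostics=diagnostics,
        samples=samples,
    )


def _grid_interval(grid: np.ndarray, mass: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    cdf = np.cumsum(mass)
    lo = float(np.interp((1 - level) / 2, cdf, grid))
    hi = float(np.interp(1 - (1 - level) / 2, cdf, grid))
    return lo, hi


# ---------------------------------------------------------------------------
# slope test, orientation, model assembly


def slope_test(fit: PosteriorFit, alpha: float = 0.01) -> str:
    """'driver_consistent' iff P(theta2 > 0) >= 1 - alpha, else 'not_consistent'."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return "driver_consistent" if fit.p_slope_positive >= 1.0 - alpha else "not_consistent"


def _pooled_slope(x: np.ndarray, y: np.ndarray) -> float:
    prior = PriorConfig()
    mode, _ = _posterior_mode(x, y.astype(float), prior)
    return float(mode[1])


def reverse_dataset(dataset: DecisionDataset, offset: float | None = None) -> DecisionDataset:
    """Map the driver to x -> offset - x (default offset: the configured
    maximum driver value).  Involution: reversing a reversed dataset with its
    recorded offset restores the original values exactly.
    """
    if dataset.orientation == "reversed":
        if offset is None and dataset.unreversed is not None:
            return dataset.unreversed
        offset = dataset.reversal_offset if offset is None else offset
        assert offset is not None
        new_orientation, new_offset = "as_is", None
    else:
        offset = dataset.x_max if offset is None else offset
        new_orientation, new_offset = "reversed", offset
    return DecisionDataset(
        decision_id=dataset.decision_id,
        driver_id=dataset.driver_id,
        x=offset - dataset.x,
        y=dataset.y.copy(),
        population=dataset.population.copy(),
        x_min=offset - dataset.x_max,
        x_max=offset - dataset.x_min,
        orientation=new_orientation,
        reversal_offset=new_offset,
        n_dropped_missing_decision=dataset.n_dropped_missing_decision,
        unreversed=dataset if new_orientation == "reversed" else None,
    )


def orient_driver(dataset: DecisionDataset) -> DecisionDataset:
    """Reverse the driver if the pooled yes-probability falls with x, so both
    populations can be fitted with a positive slope; otherwise unchanged.
    """
    slope = _pooled_slope(dataset.x, dataset.y)
    if slope >= 0:
        return dataset
    return reverse_dataset(dataset)


def build_sdt_model(
    fit_s1: PosteriorFit,
    fit_s2: PosteriorFit,
    x_min: float,
    x_max: float,
    *,
    alpha: float = 0.01,
    estimate: str = "mode",
    allow_inconsistent: bool = False,
    orientation: str = "as_is",
    reversal_offset: float | None = None,
) -> SdtModel:
    """Assemble the two-component model from per-population fits.

    Components use mu = -theta1/theta2 and s = 1/theta2 from the requested
    point estimate ('mode' = posterior mode, default; 'mle' also reported by
    the fits).  Both populations must pass the slope test unless
    ``allow_inconsistent`` marks the model as exploratory.
    """
    failing = [
        f.population for f in (fit_s1, fit_s2) if slope_test(f, alpha) == "not_consistent"
    ]
    if failing and not allow_inconsistent:
        raise ValueError(
            f"slope not distinguishable from zero for population(s) {', '.join(failing)}; "
            "the data are not consistent with this driver (pass "
            "allow_inconsistent=True for an exploratory model)"
        )
    if estimate == "mode":
        pick = lambda f: (f.theta1_hat, f.theta2_hat)
    elif estimate == "mle":
        pick = lambda f: (f.theta1_mle, f.theta2_mle)
    else:
        raise ValueError(f"unknown estimate {estimate!r}")
    comps = []
    for f in (fit_s1, fit_s2):
        t1, t2 = pick(f)
        if t2 <= 0:
            raise ValueError(
                f"population {f.population}: point estimate of the slope is non-positive; "
                "orient the driver first"
            )
        comps.append(LogisticComponent.from_theta(t1, t2))
    return SdtModel(
        s1=comps[0],
        s2=comps[1],
        x_min=float(x_min),
        x_max=float(x_max),
        orientation=orientation,
        reversal_offset=reversal_offset,
    )
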