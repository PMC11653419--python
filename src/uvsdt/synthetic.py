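"""Synthetic tinnitus-cohort generator with known ground truth.

Emulates the data-generating assumptions behind the decision analysis so
every pipeline stage can be tested without clinical data:

* membership: each participant is S2 (clinically important THI improvement,
  change < -7 points) with base rate ``p_s2``, else S1;
* drivers: hearing loss uniform on a bounded dB HL range, baseline THI built
  from tinnitus-duration and non-hearing-problem category effects plus
  noise, bounded to the score range;
* decisions: for each treatment option the yes-probability follows the
  membership-specific logistic curve expit(theta1 + theta2 * x) of that
  option's driver; options are conditionally independent given membership
  and drivers unless a joint-correlation knob is set;
* outcomes: the THI change is drawn from a shifted-exponential tail on the
  membership's side of the -7 boundary, truncated to keep both scores inside
  [0, 100] *without* flipping the label (applying the MCID labelling rule to
  the generated scores reproduces membership for every row);
* missingness: configurable per-column MCAR rates (defaults mirror the
  observed response rates: 97% baseline THI, 63% post THI, 56% GHSI).

Scores are kept continuous so the strict MCID boundary is almost surely
never hit exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import MCID, validate_cohort

__all__ = [
    "DecisionSpec",
    "GroundTruth",
    "simulate_cohort",
    "inject_mcar",
    "DEFAULT_MISSING_RATES",
]

DEFAULT_MISSING_RATES = {
    "thi_baseline": 0.03,
    "thi_post": 0.37,
    "ghsi_baseline": 0.44,
}


@dataclass(frozen=True)
class DecisionSpec:
    """Per-decision generating parameters: driver and per-population
    logistic-regression coefficients (theta1 intercept, theta2 slope)."""

    driver: str
    theta_s1: tuple[float, float]
    theta_s2: tuple[float, float]


@dataclass(frozen=True)
class GroundTruth:
    """Generating conditions for one synthetic cohort.

    Defaults correspond to a 145-participant clinical cohort: equal odds of
    a clinically important improvement, hearing loss spanning 5-115 dB HL,
    and an evaluation-period decision driven by hearing loss at
    theta = (-2, 0.05)/( -1, 0.05) (i.e. mu = 40/20 dB, s = 20 dB) with a
    counseling decision driven by baseline THI with unequal scales.
    """

    n: int = 145
    p_s2: float = 0.5
    mcid: float = MCID
    hearing_loss_bounds: tuple[float, float] = (5.0, 115.0)
    thi_bounds: tuple[float, float] = (0.0, 100.0)
    sedep: DecisionSpec = DecisionSpec(
        driver="hearing_loss", theta_s1=(-2.0, 0.05), theta_s2=(-1.0, 0.05)
    )
    pcu: DecisionSpec = DecisionSpec(
        driver="thi_baseline", theta_s1=(-3.0, 0.04), theta_s2=(-2.0, 0.05)
    )
    p_sedu_given_sedep: float = 0.58
    # shifted-exponential tail scales for the THI change on either side of
    # the -MCID boundary (points); chosen to reproduce an observed spread of
    # roughly -56 .. +28 points
    change_scale_s1: float = 7.0
    change_scale_s2: float = 10.0
    decision_correlation: float = 0.0  # Gaussian-copula correlation knob
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_s2 < 1:
            raise ValueError("p_s2 must be in (0, 1)")
        if self.mcid <= 0:
            raise ValueError("mcid must be positive")
        if self.mcid >= self.thi_bounds[1] - self.thi_bounds[0]:
            raise ValueError("mcid exceeds the representable score range")
        for k, v in self.missing_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"missing rate for {k} must be in [0, 1]")
        if not -1 < self.decision_correlation < 1:
            raise ValueError("decision_correlation must be in (-1, 1)")


def _truncated_exponential(rng, scale: float, cap: np.ndarray) -> np.ndarray:
    """Draws from Exp(scale) truncated to (0, cap], via inverse CDF."""
    cap = np.asarray(cap, dtype=float)
    if np.any(cap <= 0):
        raise ValueError("truncation cap must be positive")
    u = rng.uniform(np.finfo(float).tiny, 1.0, size=cap.shape)
    return -scale * np.log1p(-u * (-np.expm1(-cap / scale)))


def simulate_cohort(
    truth: GroundTruth, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an observable cohort table and its ground-truth table.

    Returns ``(cohort, truth_table)``: the cohort has MCAR missingness
    injected at ``truth.missing_rates``; the truth table keeps the complete
    scores and the S1/S2 membership for oracle checks.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    n = truth.n

    member_s2 = rng.random(n) < truth.p_s2
    population = np.where(member_s2, "S2", "S1")

    # covariates
    age = np.clip(rng.normal(57.0, 13.0, n), 18.0, 90.0)
    sex = rng.choice(["male", "female"], size=n, p=[0.57, 0.43])
    duration = rng.choice(["<=2mo", "2-6mo", ">6mo"], size=n, p=[0.03, 0.10, 0.87])
    nhp = rng.choice(
        ["none", "family", "work", "personality"], size=n, p=[0.66, 0.24, 0.03, 0.07]
    )
    ttype = rng.choice(["tonal", "noise", "different"], size=n, p=[0.28, 0.46, 0.26])
    specialty = rng.choice(["gp", "orl", "missing"], size=n, p=[0.26, 0.52, 0.22])

    hl_lo, hl_hi = truth.hearing_loss_bounds
    hearing_loss = rng.uniform(hl_lo, hl_hi, n)

    # baseline THI with category structure the imputation screen can find
    dur_eff = pd.Series(duration).map({"<=2mo": 0.0, "2-6mo": 4.0, ">6mo": 8.0}).to_numpy()
    nhp_eff = (
        pd.Series(nhp)
        .map({"none": 0.0, "family": 12.0, "work": 14.0, "personality": 20.0})
        .to_numpy()
    )
    thi_raw = 22.0 + dur_eff + nhp_eff + rng.normal(0.0, 16.0, n)
    lo_b, hi_b = truth.thi_bounds
    # S2 members need enough headroom below baseline for a > MCID improvement
    base_lo = np.where(member_s2, lo_b + truth.mcid + 1.0, lo_b)
    thi_baseline = np.clip(thi_raw, base_lo, hi_b - 3.0)

    ghsi = np.clip(
        85.0 - 0.45 * thi_baseline - 0.15 * age + rng.normal(0.0, 8.0, n), 0.0, 100.0
    )

    # THI change: shifted-exponential tails on either side of the -MCID
    # boundary, truncated to keep thi_post in bounds without flipping labels
    change = np.empty(n)
    cap_s2 = thi_baseline[member_s2] - truth.mcid - lo_b  # room below -MCID
    change[member_s2] = -truth.mcid - _truncated_exponential(rng, truth.change_scale_s2, cap_s2)
    room_s1 = hi_b - thi_baseline[~member_s2] + truth.mcid  # room above -MCID
    lo_e = np.maximum(0.0, truth.mcid - (thi_baseline[~member_s2] - lo_b))
    e_s1 = lo_e + _truncated_exponential(rng, truth.change_scale_s1, room_s1 - lo_e)
    change[~member_s2] = -truth.mcid + e_s1
    thi_post = thi_baseline + change

    # decisions from the membership-specific logistic curves
    from scipy.special import expit, ndtr

    drivers = {"hearing_loss": hearing_loss, "thi_baseline": thi_baseline}
    probs = {}
    for name, spec in (("SEDEP", truth.sedep), ("PCU", truth.pcu)):
        x = drivers[spec.driver]
        t1 = np.where(member_s2, spec.theta_s2[0], spec.theta_s1[0])
        t2 = np.where(member_s2, spec.theta_s2[1], spec.theta_s1[1])
        probs[name] = expit(t1 + t2 * x)
    rho = truth.decision_correlation
    if rho == 0.0:
        u_sedep = rng.random(n)
        u_pcu = rng.random(n)
    else:
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        u_sedep, u_pcu = ndtr(z[:, 0]), ndtr(z[:, 1])
    sedep = np.where(u_sedep < probs["SEDEP"], "yes", "no")
    pcu = np.where(u_pcu < probs["PCU"], "yes", "no")
    sedu = np.where(
        sedep == "yes",
        np.where(rng.random(n) < truth.p_sedu_given_sedep, "yes", "no"),
        "not_applicable",
    )

    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "hearing_loss": hearing_loss,
            "thi_baseline": thi_baseline,
            "thi_post": thi_post,
            "ghsi_baseline": ghsi,
            "decision_sedep": sedep,
            "decision_sedu": sedu,
            "decision_pcu": pcu,
            "tinnitus_duration": duration,
            "non_hearing_problems": nhp,
            "tinnitus_type": ttype,
            "referring_specialty": specialty,
        }
    )
    validate_cohort(cohort)

    truth_table = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"],
            "population": population,
            "thi_baseline_true": thi_baseline,
            "thi_post_true": thi_post,
            "thi_change_true": change,
            "ghsi_true": ghsi,
            "seed": seed,
        }
    )

    cohort = inject_mcar(cohort, truth.missing_rates, seed=rng.integers(0, 2**31 - 1))
    return cohort, truth_table


def inject_mcar(df: pd.DataFrame, rates: dict, seed: int | None = None) -> pd.DataFrame:
    """Set each targeted cell missing independently with its column rate.

    Missingness is independent of every observed and unobserved value (MCAR
    by construction).
    """
    rng = np.random.default_rng(seed)
    out = df.copy()
    for col, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"rate for {col} must be in [0, 1]")
        if col not in out.columns:
            raise KeyError(f"column {col!r} not in table")
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out
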