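"""Single-imputation chain with two-stage ANOVA predictor screening.

Missing questionnaire scores are filled by conditional-mean prediction from
ordinary least squares models fitted on the observed rows:

1. *Screening stage 1* — a joint linear model of the target on all candidate
   predictors; type-III F-tests (full vs. reduced model, sum-to-zero
   contrasts for categorical terms) keep candidates with p < 0.15.
2. *Screening stage 2* — refit on the survivors; keep p < 0.05.
3. *Imputation* — OLS on the kept predictors (reference coding), point
   prediction of missing cells, clamped to the score range.  No residual
   noise is added by default, matching a single conditional-mean imputation;
   an optional noise draw exists for sensitivity analyses.

Targets are processed in order, and earlier imputed targets become eligible
candidates for later ones (baseline THI -> baseline GHSI -> post-treatment
THI in the default chain).  Single imputation understates downstream
uncertainty; this is a documented property of the procedure, not a bug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Candidate",
    "ScreeningResult",
    "ImputationModel",
    "ChainStep",
    "ImputationReport",
    "screen_predictors",
    "fit_imputation_model",
    "impute_chain",
    "default_chain",
]


@dataclass(frozen=True)
class Candidate:
    name: str
    kind: str  # "continuous" | "categorical"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"candidate kind must be continuous/categorical, got {self.kind!r}")


@dataclass
class ScreeningResult:
    target: str
    stage1: list[tuple[str, float, float, bool]]  # (candidate, F, p, kept)
    stage2: list[tuple[str, float, float, bool]]
    n_rows: int

    @property
    def kept(self) -> list[str]:
        return [name for name, _, _, keep in self.stage2 if keep]


@dataclass
class ImputationModel:
    target: str
    predictors: list[Candidate]
    coefficients: dict[str, float]
    r2_adjusted: float
    rmse: float
    n_fit: int
    _result: object = field(default=None, repr=False)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if self._result is None:  # intercept-only fallback
            return np.full(len(df), self.coefficients["Intercept"])
        return np.asarray(self._result.predict(df), dtype=float)


@dataclass(frozen=True)
class ChainStep:
    target: str
    candidates: tuple[Candidate, ...]
    p1: float = 0.15
    p2: float = 0.05
    clamp: tuple[float, float] | None = (0.0, 100.0)


@dataclass
class ImputationReport:
    steps: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for step in self.steps:
            scr: ScreeningResult | None = step.get("screening")
            model: ImputationModel | None = step.get("model")
            for stage, entries in (("1", scr.stage1 if scr else []), ("2", scr.stage2 if scr else [])):
                for name, f_stat, p, keep in entries:
                    rows.append(
                        {
                            "target": step["target"],
                            "stage": stage,
                            "predictor": name,
                            "F": f_stat,
                            "p": p,
                            "kept": keep,
                            "r2_adjusted": model.r2_adjusted if model else np.nan,
                            "rmse": model.rmse if model else np.nan,
                            "n_imputed": step.get("n_imputed", 0),
                            "note": step.get("note", ""),
                        }
                    )
            if not (scr and (scr.stage1 or scr.stage2)):
                rows.append(
                    {
                        "target": step["target"],
                        "stage": "-",
                        "predictor": "-",
                        "F": np.nan,
                        "p": np.nan,
                        "kept": False,
                        "r2_adjusted": model.r2_adjusted if model else np.nan,
                        "rmse": model.rmse if model else np.nan,
                        "n_imputed": step.get("n_imputed", 0),
                        "note": step.get("note", ""),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# formula helpers


def _term(c: Candidate) -> str:
    if c.kind == "categorical":
        return f"C(Q('{c.name}'), Sum)"
    return f"Q('{c.name}')"


def _term_reference(c: Candidate) -> str:
    if c.kind == "categorical":
        return f"C(Q('{c.name}'))"
    return f"Q('{c.name}')"


def _drop_aliased(df: pd.DataFrame, target: str, candidates: list[Candidate]) -> list[Candidate]:
    """Drop candidates that add no rank to the design (constant columns or
    perfect collinearity), with a warning naming the dropped terms."""
    import patsy

    kept: list[Candidate] = []
    dropped: list[str] = []
    for c in candidates:
        col = df[c.name]
        if col.nunique(dropna=True) < 2:
            dropped.append(c.name)
            continue
        trial = kept + [c]
        formula = " + ".join(_term(t) for t in trial)
        mat = patsy.dmatrix(formula, df, return_type="matrix")
        if np.linalg.matrix_rank(np.asarray(mat)) < mat.shape[1]:
            dropped.append(c.name)
            continue
        kept.append(c)
    if dropped:
        warnings.warn(
            f"aliased/degenerate predictor(s) dropped for target {target!r}: {dropped}",
            stacklevel=3,
        )
    return kept


def _anova_type3(df: pd.DataFrame, target: str, candidates: list[Candidate]) -> list[tuple[str, float, float]]:
    """Per-candidate type-III F-tests via full-vs-reduced model comparison
    with sum-to-zero contrasts."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rhs = " + ".join(_term(c) for c in candidates)
    full = smf.ols(f"Q('{target}') ~ {rhs}", data=df).fit()
    out = []
    for c in candidates:
        others = [t for t in candidates if t is not c]
        rhs_red = " + ".join(_term(t) for t in others) if others else "1"
        reduced = smf.ols(f"Q('{target}') ~ {rhs_red}", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = anova_lm(reduced, full)
        out.append((c.name, float(tab["F"].iloc[1]), float(tab["Pr(>F)"].iloc[1])))
    return out


# ---------------------------------------------------------------------------
# operations


def screen_predictors(
    df: pd.DataFrame,
    target: str,
    candidates: list[Candidate] | tuple[Candidate, ...],
    p1: float = 0.15,
    p2: float = 0.05,
    min_rows: int = 20,
) -> ScreeningResult:
    """Two-stage predictor screening for one imputation target.

    Stage 1 keeps candidates with a type-III p < ``p1`` in the joint model;
    stage 2 refits on the survivors and keeps p < ``p2``.  Deterministic
    given the table.  Rows are those where the target and all continuous
    candidates are observed; missing categorical entries must already be
    coded as an explicit level.
    """
    candidates = list(candidates)
    rows = df[df[target].notna()].copy()
    for c in candidates:
        if c.kind == "continuous":
            rows = rows[rows[c.name].notna()]
    if len(rows) < min_rows:
        raise ValueError(
            f"only {len(rows)} usable rows to screen predictors for {target!r} "
            f"(minimum {min_rows})"
        )
    usable = _drop_aliased(rows, target, candidates)
    if not usable:
        return ScreeningResult(target=target, stage1=[], stage2=[], n_rows=len(rows))
    stage1_stats = _anova_type3(rows, target, usable)
    stage1 = [(name, f, p, p < p1) for name, f, p in stage1_stats]
    survivors = [c for c, (_, _, p) in zip(usable, stage1_stats) if p < p1]
    if not survivors:
        return ScreeningResult(target=target, stage1=stage1, stage2=[], n_rows=len(rows))
    stage2_stats = _anova_type3(rows, target, survivors)
    stage2 = [(name, f, p, p < p2) for name, f, p in stage2_stats]
    return ScreeningResult(target=target, stage1=stage1, stage2=stage2, n_rows=len(rows))


def fit_imputation_model(
    df: pd.DataFrame,
    target: str,
    predictors: list[Candidate] | tuple[Candidate, ...],
) -> ImputationModel:
    """OLS of the target on the kept predictors (reference coding).

    Reports adjusted R^2 and the residual RMSE (sqrt of SSE over residual
    degrees of freedom, the usual linear-model root mean squared error).
    An empty predictor list yields the intercept-only (grand mean) model.
    """
    import statsmodels.formula.api as smf

    predictors = list(predictors)
    rows = df[df[target].notna()].copy()
    for c in predictors:
        if c.kind == "continuous":
            rows = rows[rows[c.name].notna()]
    n_fit = len(rows)
    if not predictors:
        mean = float(rows[target].mean())
        resid = rows[target] - mean
        rmse = float(np.sqrt((resid**2).sum() / max(n_fit - 1, 1)))
        return ImputationModel(
            target=target,
            predictors=[],
            coefficients={"Intercept": mean},
            r2_adjusted=0.0,
            rmse=rmse,
            n_fit=n_fit,
        )
    predictors = _drop_aliased(rows, target, predictors)
    rhs = " + ".join(_term_reference(c) for c in predictors) if predictors else "1"
    res = smf.ols(f"Q('{target}') ~ {rhs}", data=rows).fit()
    if n_fit < len(res.params) + 2:
        raise ValueError(
            f"too few rows ({n_fit}) to fit {len(res.params)} coefficients for {target!r}"
        )
    rmse = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return ImputationModel(
        target=target,
        predictors=predictors,
        coefficients={k: float(v) for k, v in res.params.items()},
        r2_adjusted=float(res.rsquared_adj),
        rmse=rmse,
        n_fit=n_fit,
        _result=res,
    )


def impute_chain(
    df: pd.DataFrame,
    chain: list[ChainStep] | tuple[ChainStep, ...],
    *,
    add_noise: bool = False,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Run the sequential screening/fit/predict chain.

    For each step: screen -> fit on observed rows -> point-predict the
    missing cells (optionally with a residual noise draw), clamp to the
    valid range, and set the ``<target>_imputed`` flag column.  Observed
    values are never modified.  Earlier targets are imputed before later
    ones, so they are fully observed when used as candidates downstream.
    """
    out = df.copy()
    report = ImputationReport()
    rng = np.random.default_rng(seed)
    for step in chain:
        flag_col = f"{step.target}_imputed"
        missing = out[step.target].isna()
        if flag_col not in out.columns:
            out[flag_col] = False
        if missing.sum() == 0:
            report.steps.append(
                {"target": step.target, "n_imputed": 0, "note": "fully observed; skipped"}
            )
            continue
        if missing.all():
            raise ValueError(f"target {step.target!r} is fully missing; cannot impute")
        screening = screen_predictors(out, step.target, list(step.candidates), step.p1, step.p2)
        kept_names = set(screening.kept)
        kept = [c for c in step.candidates if c.name in kept_names]
        note = ""
        if not kept:
            note = "no predictor survived stage 2; grand-mean imputation"
        model = fit_imputation_model(out, step.target, kept)
        pred_rows = out.loc[missing].copy()
        # continuous predictors still missing on a prediction row fall back to
        # their observed mean for that row's prediction (logged)
        n_fallback = 0
        for c in kept:
            if c.kind == "continuous" and pred_rows[c.name].isna().any():
                n_fallback += int(pred_rows[c.name].isna().sum())
                pred_rows[c.name] = pred_rows[c.name].fillna(out[c.name].mean())
        pred = model.predict(pred_rows)
        if add_noise and model.rmse > 0:
            pred = pred + rng.normal(0.0, model.rmse, size=len(pred))
        n_clamped = 0
        if step.clamp is not None:
            lo, hi = step.clamp
            n_clamped = int(np.sum((pred < lo) | (pred > hi)))
            pred = np.clip(pred, lo, hi)
        out.loc[missing, step.target] = pred
        out.loc[missing, flag_col] = True
        if n_clamped:
            note = (note + "; " if note else "") + f"{n_clamped} prediction(s) clamped"
        if n_fallback:
            note = (note + "; " if note else "") + (
                f"{n_fallback} missing predictor cell(s) replaced by column mean"
            )
        report.steps.append(
            {
                "target": step.target,
                "screening": screening,
                "model": model,
                "n_imputed": int(missing.sum()),
                "note": note,
            }
        )
    return out, report


def default_chain() -> list[ChainStep]:
    """The standard three-step chain: baseline THI, then baseline GHSI (with
    imputed baseline THI as candidate), then post-treatment THI (with both
    imputed scores as candidates)."""
    base = [
        Candidate("age", "continuous"),
        Candidate("hearing_loss", "continuous"),
        Candidate("sex", "categorical"),
        Candidate("tinnitus_duration", "categorical"),
        Candidate("non_hearing_problems", "categorical"),
        Candidate("tinnitus_type", "categorical"),
        Candidate("referring_specialty", "categorical"),
    ]
    thi = Candidate("thi_baseline", "continuous")
    ghsi = Candidate("ghsi_baseline", "continuous")
    return [
        ChainStep(target="thi_baseline", candidates=tuple(base)),
        ChainStep(target="ghsi_baseline", candidates=tuple(base + [thi])),
        ChainStep(target="thi_post", candidates=tuple(base + [thi, ghsi])),
    ]
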