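"""End-to-end analysis pipeline and report collation.

Stages, in the order the cohort method prescribes: impute missing scores ->
label S1/S2 outcomes -> extract per-decision marginal datasets -> orient the
driver -> fit both populations with Bayesian logistic regression -> slope
test -> assemble the SDT model -> ROC/AUC, logit-ROC accuracy, likelihood
ratio and decision criteria.  Imputation precedes labelling because labels
need post-treatment scores.

Every written table carries a provenance header (package version, seed,
config hash).  A decision/driver pair whose slope test fails is reported
with the verdict "driver not consistent with SDT assumptions" and its
downstream outputs are suppressed unless the run is marked exploratory.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, cohort, impute, sdt

__all__ = ["AnalysisConfig", "PairResult", "analyze_cohort", "write_bundle", "collate_report"]

log = logging.getLogger("uvsdt")

DEFAULT_GRID_BOUNDS = {"hearing_loss": (0.0, 120.0), "thi_baseline": (0.0, 100.0)}


@dataclass
class AnalysisConfig:
    pairs: tuple[tuple[str, str], ...] = (("SEDEP", "hearing_loss"), ("PCU", "thi_baseline"))
    mcid: float = cohort.MCID
    grid_bounds: dict = field(default_factory=lambda: dict(DEFAULT_GRID_BOUNDS))
    alpha: float = 0.01
    estimate: str = "mode"
    prior: bayes.PriorConfig = field(default_factory=bayes.PriorConfig)
    sampler: bayes.SamplerConfig = field(default_factory=bayes.SamplerConfig)
    method: str = "metropolis"
    n_roc_grid: int = 512
    exploratory: bool = False
    utility: sdt.UtilityContext | None = None
    seed: int = 0


@dataclass
class PairResult:
    decision_id: str
    driver_id: str
    verdict: str  # "ok" | "driver not consistent with SDT assumptions"
    fits: dict[str, bayes.PosteriorFit]
    orientation: str
    reversal_offset: float | None
    model: sdt.SdtModel | None = None
    auc_partial: float | None = None
    auc_closed: float | None = None
    logit: sdt.LogitRoc | None = None
    unbiased: sdt.CriterionResult | None = None
    extremum: tuple[float, float, str] | None = None
    beta: float | None = None
    beta_criterion: sdt.CriterionResult | None = None


def analyze_pair(
    df: pd.DataFrame, decision_id: str, driver_id: str, config: AnalysisConfig
) -> PairResult:
    bounds = config.grid_bounds.get(driver_id)
    ds = cohort.extract_decision_dataset(
        df, decision_id, driver_id, mcid=config.mcid, bounds=bounds
    )
    ds = bayes.orient_driver(ds)
    fits = {}
    for i, pop in enumerate(("S1", "S2")):
        x, y = ds.subset(pop)
        fits[pop] = bayes.fit_population(
            x,
            y,
            population=pop,
            prior=config.prior,
            sampler=config.sampler,
            seed=(config.seed * 4 + i + zlib.crc32(f"{decision_id}/{driver_id}".encode()) % 997)
            % (2**31 - 1),
            method=config.method,
        )
    failing = [p for p in ("S1", "S2") if bayes.slope_test(fits[p], config.alpha) == "not_consistent"]
    result = PairResult(
        decision_id=decision_id,
        driver_id=driver_id,
        verdict="ok" if not failing else "driver not consistent with SDT assumptions",
        fits=fits,
        orientation=ds.orientation,
        reversal_offset=ds.reversal_offset,
    )
    if failing and not config.exploratory:
        log.warning(
            "%s/%s: slope test failed for %s; downstream outputs suppressed",
            decision_id,
            driver_id,
            failing,
        )
        return result
    model = bayes.build_sdt_model(
        fits["S1"],
        fits["S2"],
        ds.x_min,
        ds.x_max,
        alpha=config.alpha,
        estimate=config.estimate,
        allow_inconsistent=config.exploratory,
        orientation=ds.orientation,
        reversal_offset=ds.reversal_offset,
    )
    roc = sdt.roc_curve(model, n_grid=config.n_roc_grid)
    result.model = model
    result.auc_partial = sdt.auc(roc, mode="partial")
    result.auc_closed = sdt.auc(roc, mode="closed")
    result.logit = sdt.logit_roc(model, n_grid=config.n_roc_grid)
    result.unbiased = sdt.unbiased_criterion(model)
    result.extremum = sdt.lr_extremum(model)
    if config.utility is not None:
        result.beta = sdt.optimal_beta(config.utility)
        result.beta_criterion = sdt.criterion_for_beta(model, result.beta)
    return result


def analyze_cohort(
    df: pd.DataFrame,
    config: AnalysisConfig | None = None,
    chain: list[impute.ChainStep] | None = None,
) -> tuple[list[PairResult], impute.ImputationReport, pd.DataFrame]:
    """Impute, then analyze every configured decision/driver pair.

    Returns (pair results, imputation report, imputed table).
    """
    config = config or AnalysisConfig()
    chain = chain if chain is not None else impute.default_chain()
    imputed, report = impute.impute_chain(df, chain)
    results = [analyze_pair(imputed, d, drv, config) for d, drv in config.pairs]
    return results, report, imputed


# ---------------------------------------------------------------------------
# bundle output


def _provenance(config: AnalysisConfig) -> str:
    from . import __version__
    from .cohort import _config_hash

    return f"# uvsdt {__version__} seed={config.seed} config={_config_hash(config)}\n"


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    path.write_text(header + df.to_csv(index=False))


def write_bundle(
    results: list[PairResult],
    report: impute.ImputationReport,
    outdir: str | Path,
    config: AnalysisConfig,
) -> Path:
    """Write the per-pair result tables and a machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    _write_csv(report.to_frame(), outdir / "imputation_report.csv", header)
    for r in results:
        tag = f"{r.decision_id}_{r.driver_id}".lower()
        post_rows = []
        for pop, f in r.fits.items():
            post_rows.append(
                {
                    "population": pop,
                    "theta1_mode": f.theta1_hat,
                    "theta2_mode": f.theta2_hat,
                    "theta1_mle": f.theta1_mle,
                    "theta2_mle": f.theta2_mle,
                    "bci_theta1_lo": f.bci_theta1[0],
                    "bci_theta1_hi": f.bci_theta1[1],
                    "bci_theta2_lo": f.bci_theta2[0],
                    "bci_theta2_hi": f.bci_theta2[1],
                    "p_slope_positive": f.p_slope_positive,
                    "verdict": bayes.slope_test(f, config.alpha),
                    "seed": f.seed,
                    "prior": f.prior.describe(),
                }
            )
        _write_csv(pd.DataFrame(post_rows), outdir / f"{tag}_posterior.csv", header)
        lines = [
            f"decision={r.decision_id}",
            f"driver={r.driver_id}",
            f"verdict={r.verdict}",
            f"orientation={r.orientation}",
            f"reversal_offset={r.reversal_offset}",
            f"seed={config.seed}",
        ]
        if r.model is not None:
            m = r.model
            grid = np.linspace(m.x_min, m.x_max, config.n_roc_grid)
            curves = pd.DataFrame(
                {
                    "x": grid,
                    "cdf_s1": sdt.cdf(m.s1, grid),
                    "cdf_s2": sdt.cdf(m.s2, grid),
                    "pdf_s1": sdt.pdf(m.s1, grid),
                    "pdf_s2": sdt.pdf(m.s2, grid),
                    "lr": sdt.likelihood_ratio(m, grid),
                }
            )
            _write_csv(curves, outdir / f"{tag}_curves.csv", header)
            roc = sdt.roc_curve(m, n_grid=config.n_roc_grid)
            _write_csv(
                pd.DataFrame({"criterion": roc.criterion, "fp": roc.fp, "tp": roc.tp}),
                outdir / f"{tag}_roc.csv",
                header,
            )
            assert r.logit is not None and r.unbiased is not None
            lines += [
                f"mu_s1={m.s1.mu}",
                f"s_s1={m.s1.s}",
                f"mu_s2={m.s2.mu}",
                f"s_s2={m.s2.s}",
                f"auc_partial={r.auc_partial}",
                f"auc_closed={r.auc_closed}",
                f"logit_roc_slope={r.logit.slope}",
                f"accuracy_index={r.logit.intercept}",
                f"unbiased_criterion={','.join(f'{v}' for v in r.unbiased.values()) or 'none'}",
                f"criterion_always={r.unbiased.always}",
                f"lr_extremum={r.extremum}",
            ]
            if r.beta is not None and r.beta_criterion is not None:
                lines += [
                    f"optimal_beta={r.beta}",
                    f"beta_criterion={','.join(f'{v}' for v in r.beta_criterion.values()) or 'none'}",
                ]
        (outdir / f"{tag}_summary.txt").write_text(header + "\n".join(lines) + "\n")
    return outdir


def collate_report(bundle_dir: str | Path) -> pd.DataFrame:
    """Collate the per-pair summary files of a bundle into one table."""
    bundle_dir = Path(bundle_dir)
    rows = []
    for path in sorted(bundle_dir.glob("*_summary.txt")):
        entry: dict[str, object] = {}
        for line in path.read_text().splitlines():
            if line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            entry[k] = v
        if "verdict" in entry and entry["verdict"] != "ok":
            entry["flag"] = "suppressed"
        rows.append(entry)
    if not rows:
        log.warning("no summary files found in %s", bundle_dir)
        return pd.DataFrame()
    return pd.DataFrame(rows)
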