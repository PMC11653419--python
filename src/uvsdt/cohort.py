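"""Cohort schema, delimited-text I/O, outcome labelling and marginal extraction.

One row per participant: the yes/no decisions for each treatment option
(starting a sound-enrichment-device evaluation period, SEDEP; purchasing the
device afterwards, SEDU; psychosocial counseling uptake, PCU), the continuous
decision drivers (hearing loss in dB HL at 8 kHz worst ear; baseline THI
score), the outcome scores (baseline and post-treatment THI, 0-100), and the
auxiliary covariates the imputation chain screens.

Participants are labelled S2 when their THI score improved by strictly more
than the minimal clinically important difference (7 points, i.e. change
< -7), else S1.  Per-decision datasets are the marginals of the SEDEP x PCU
joint: collapsing over the other decision, dropping rows where the target
decision is missing.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA",
    "FieldSpec",
    "DecisionDataset",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "label_outcome",
    "label_outcomes",
    "extract_decision_dataset",
    "marginal_counts",
    "MCID",
    "DECISION_COLUMNS",
    "DRIVER_COLUMNS",
]

MCID = 7.0  # minimal clinically important THI change, points

DECISION_COLUMNS = {
    "SEDEP": "decision_sedep",
    "SEDU": "decision_sedu",
    "PCU": "decision_pcu",
}
DRIVER_COLUMNS = ("hearing_loss", "thi_baseline")


@dataclass(frozen=True)
class FieldSpec:
    kind: str  # "id" | "numeric" | "categorical"
    bounds: tuple[float, float] | None = None
    levels: tuple[str, ...] | None = None
    nullable: bool = False
    # categorical fields where a missing entry is itself a recorded level
    missing_level: bool = False


SCHEMA: dict[str, FieldSpec] = {
    "participant_id": FieldSpec("id"),
    "age": FieldSpec("numeric", bounds=(18.0, 120.0)),
    "sex": FieldSpec("categorical", levels=("male", "female", "missing"), missing_level=True),
    "hearing_loss": FieldSpec("numeric", bounds=(-10.0, 130.0), nullable=True),
    "thi_baseline": FieldSpec("numeric", bounds=(0.0, 100.0), nullable=True),
    "thi_post": FieldSpec("numeric", bounds=(0.0, 100.0), nullable=True),
    "ghsi_baseline": FieldSpec("numeric", bounds=(0.0, 100.0), nullable=True),
    "decision_sedep": FieldSpec("categorical", levels=("yes", "no"), nullable=True),
    "decision_sedu": FieldSpec(
        "categorical", levels=("yes", "no", "not_applicable"), nullable=True
    ),
    "decision_pcu": FieldSpec("categorical", levels=("yes", "no"), nullable=True),
    "tinnitus_duration": FieldSpec("categorical", levels=("<=2mo", "2-6mo", ">6mo")),
    "non_hearing_problems": FieldSpec(
        "categorical", levels=("none", "family", "work", "personality")
    ),
    "tinnitus_type": FieldSpec("categorical", levels=("tonal", "noise", "different")),
    "referring_specialty": FieldSpec(
        "categorical", levels=("gp", "orl", "missing"), missing_level=True
    ),
}


class CohortValidationError(ValueError):
    """Validation failure; carries (row, column, value, message) diagnostics."""

    def __init__(self, problems: list[tuple[int | None, str, object, str]]):
        self.problems = problems
        lines = [
            f"  row {r if r is not None else '-'}, column {c!r}, value {v!r}: {m}"
            for r, c, v, m in problems[:20]
        ]
        more = "" if len(problems) <= 20 else f"\n  ... and {len(problems) - 20} more"
        super().__init__("cohort validation failed:\n" + "\n".join(lines) + more)


@dataclass
class DecisionDataset:
    """Per-(decision, driver) marginal dataset for the SDT analysis."""

    decision_id: str
    driver_id: str
    x: np.ndarray
    y: np.ndarray  # 1 = yes, 0 = no
    population: np.ndarray  # "S1" / "S2"
    x_min: float
    x_max: float
    orientation: str = "as_is"
    reversal_offset: float | None = None
    n_dropped_missing_decision: int = 0
    # pre-reversal dataset, kept so un-reversing restores values bit-exactly
    unreversed: "DecisionDataset | None" = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.population = np.asarray(self.population, dtype=object)
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("responses must be binary 0/1")
        if len(self.x) != len(self.y) or len(self.x) != len(self.population):
            raise ValueError("x, y and population must have equal length")
        if len(self.x) and (self.x.min() < self.x_min or self.x.max() > self.x_max):
            raise ValueError("driver values outside declared [x_min, x_max]")

    def subset(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.population == population
        return self.x[mask], self.y[mask]


# ---------------------------------------------------------------------------
# I/O


def _config_hash(obj: object) -> str:
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:10]


def read_cohort(
    path: str | Path | io.TextIOBase,
    *,
    delimiter: str = ",",
    na_token: str = "NA",
    column_map: Mapping[str, str] | None = None,
    validate: bool = True,
) -> pd.DataFrame:
    """Read a delimited cohort table and validate it against the schema.

    ``column_map`` maps file header names to schema field names.  Missing
    values are encoded by ``na_token``; for categorical fields that carry an
    explicit 'missing' level (sex, referring specialty) the token is mapped
    to that level instead of NaN.  A leading provenance comment line
    (starting with '#') is skipped.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    lines = text.splitlines(True)
    while lines and lines[0].startswith("#"):
        lines.pop(0)
    df = pd.read_csv(
        io.StringIO("".join(lines)),
        sep=delimiter,
        na_values=[na_token],
        keep_default_na=False,
        dtype={"participant_id": str},
    )
    if column_map:
        df = df.rename(columns=dict(column_map))
    unknown = [c for c in df.columns if c not in SCHEMA and not c.endswith("_imputed")]
    if unknown:
        raise CohortValidationError(
            [(None, c, None, "unknown column (not in schema, no mapping given)") for c in unknown]
        )
    for name, spec in SCHEMA.items():
        if name not in df.columns:
            continue
        if spec.kind == "numeric":
            df[name] = pd.to_numeric(df[name])
        elif spec.missing_level:
            df[name] = df[name].fillna("missing")
    for c in df.columns:
        if c.endswith("_imputed"):
            df[c] = df[c].astype(bool)
    if validate:
        validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema invariants; raise CohortValidationError naming each cell."""
    problems: list[tuple[int | None, str, object, str]] = []
    for name, spec in SCHEMA.items():
        if name not in df.columns:
            continue
        col = df[name]
        if spec.kind == "numeric":
            lo, hi = spec.bounds if spec.bounds else (-np.inf, np.inf)
            bad = col.notna() & ((col < lo) | (col > hi))
            for idx in df.index[bad]:
                problems.append((int(idx), name, col[idx], f"outside [{lo}, {hi}]"))
        elif spec.kind == "categorical":
            ok = set(spec.levels or ())
            bad = col.notna() & ~col.isin(ok)
            for idx in df.index[bad]:
                problems.append((int(idx), name, col[idx], f"not one of {sorted(ok)}"))
    # device purchase requires an evaluation period first
    if "decision_sedu" in df.columns and "decision_sedep" in df.columns:
        bad = (df["decision_sedu"] == "yes") & (df["decision_sedep"] != "yes")
        for idx in df.index[bad]:
            problems.append(
                (int(idx), "decision_sedu", "yes", "device purchase without evaluation period")
            )
    if problems:
        raise CohortValidationError(problems)
    return df


def write_cohort(
    df: pd.DataFrame,
    path: str | Path,
    *,
    delimiter: str = ",",
    na_token: str = "NA",
    seed: int | None = None,
    config: object = None,
) -> None:
    """Write the cohort with a provenance header comment line.

    Round-trips bit-exactly through :func:`read_cohort` (float columns are
    written at full repr precision).
    """
    from . import __version__

    header = f"# uvsdt {__version__} seed={seed} config={_config_hash(config)}\n"
    body = df.to_csv(index=False, sep=delimiter, na_rep=na_token)
    Path(path).write_text(header + body)


# ---------------------------------------------------------------------------
# outcome labelling


def label_outcome(thi_baseline: float, thi_post: float, mcid: float = MCID) -> str:
    """S2 iff the THI score decreased by strictly more than ``mcid`` points.

    A change of exactly -mcid is S1 (the improvement must exceed the MCID).
    Invariant under adding the same constant to both scores.
    """
    if mcid <= 0:
        raise ValueError("mcid must be positive")
    if thi_baseline is None or thi_post is None or np.isnan(thi_baseline) or np.isnan(thi_post):
        raise ValueError(
            "cannot label outcome with missing THI scores; run the imputation chain first"
        )
    return "S2" if (thi_post - thi_baseline) < -mcid else "S1"


def label_outcomes(df: pd.DataFrame, mcid: float = MCID) -> pd.Series:
    """Vectorized S1/S2 labels; errors if any used score is missing."""
    if df["thi_baseline"].isna().any() or df["thi_post"].isna().any():
        n = int(df["thi_baseline"].isna().sum() + df["thi_post"].isna().sum())
        raise ValueError(
            f"{n} missing THI scores; impute before labelling outcomes"
        )
    change = df["thi_post"] - df["thi_baseline"]
    return pd.Series(np.where(change < -mcid, "S2", "S1"), index=df.index, name="population")


# ---------------------------------------------------------------------------
# marginal extraction


def marginal_counts(df: pd.DataFrame, decision_id: str) -> tuple[int, int]:
    """(yes, no) counts for one decision, collapsed over the other decision."""
    col = DECISION_COLUMNS[decision_id]
    present = df[col].isin(["yes", "no"])
    yes = int((df.loc[present, col] == "yes").sum())
    return yes, int(present.sum()) - yes


def extract_decision_dataset(
    df: pd.DataFrame,
    decision_id: str,
    driver_id: str,
    *,
    mcid: float = MCID,
    bounds: tuple[float, float] | None = None,
    min_per_population: int = 5,
) -> DecisionDataset:
    """Marginal (x, y, population) dataset for one decision/driver pair.

    y = 1 iff the participant chose yes on ``decision_id`` regardless of the
    other decision (the 2x2 joint collapsed over the other axis).  Rows with
    a missing target decision or driver are dropped (and counted); rows with
    missing outcome scores raise, since S1/S2 labels need both.
    """
    if decision_id not in DECISION_COLUMNS:
        raise KeyError(f"unknown decision {decision_id!r}")
    if driver_id not in DRIVER_COLUMNS:
        raise KeyError(f"unknown driver {driver_id!r}")
    col = DECISION_COLUMNS[decision_id]
    usable = df[col].isin(["yes", "no"]) & df[driver_id].notna()
    dropped = int(len(df) - usable.sum())
    sub = df.loc[usable]
    population = label_outcomes(sub, mcid=mcid).to_numpy()
    x = sub[driver_id].to_numpy(dtype=float)
    y = (sub[col] == "yes").to_numpy().astype(int)
    for pop in ("S1", "S2"):
        n_pop = int((population == pop).sum())
        if n_pop < min_per_population:
            raise ValueError(
                f"population {pop} has {n_pop} observations for {decision_id}/{driver_id} "
                f"(minimum {min_per_population}); population {pop} "
                + ("empty" if n_pop == 0 else "too small")
            )
    if bounds is None:
        x_min, x_max = float(x.min()), float(x.max())
    else:
        x_min, x_max = map(float, bounds)
    return DecisionDataset(
        decision_id=decision_id,
        driver_id=driver_id,
        x=x,
        y=y,
        population=population,
        x_min=x_min,
        x_max=x_max,
        n_dropped_missing_decision=dropped,
    )
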