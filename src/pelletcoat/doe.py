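"""Optimal-design regression for fluid-bed coating experiments.

The coating study varies three factors over a 2x3x3 categorical domain:

* **A** — coating polymer: Kollicoat Protect or Kollidon VA64
* **B** — polymer concentration: 1.0, 2.5 or 5.0 % w/v
* **C** — coating-suspension-to-pellets ratio: 1:1, 2:1 or 3:1 (mL/g)

The response is the total coated surface of the pellets in percent,
measured by RGB image analysis (:mod:`pelletcoat.imaging`).  A 20-run
IV-optimal subset of the full factorial is analysed with an ordinary
least-squares model on categorical contrast codes::

    y = b0 + bA*A + bB1*B1 + bB2*B2 + bC1*C1 + bC2*C2
           + AB and BC interaction terms

where the two-level factor A is coded -1/+1 and each three-level factor
is expanded into two contrast columns taking values in {1, 0, -1}
(level 1 -> (1, 0), level 2 -> (0, 1), level 3 -> (-1, -1)).  The model
contains main effects plus the AB and BC interactions only — twelve
parameters in total.  Model quality is summarised by R², adjusted R² and
predicted R² (from the leave-one-out PRESS statistic), and factor
significance by partial (Type III) F-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POLYMERS",
    "CONCENTRATIONS",
    "RATIOS",
    "TERM_NAMES",
    "FactorLevels",
    "CodedModel",
    "AnovaRow",
    "load_coating_design",
    "validate_design_table",
    "encode_run",
    "build_design_matrix",
    "fit_model",
    "anova",
    "r_squared_suite",
    "predict",
    "optimize",
    "full_factorial",
]

POLYMERS = ("Kollicoat Protect", "Kollidon VA64")
CONCENTRATIONS = (1.0, 2.5, 5.0)
RATIOS = ("1:1", "2:1", "3:1")

#: Model terms, in design-matrix column order.
TERM_NAMES = (
    "intercept",
    "A",
    "B1",
    "B2",
    "C1",
    "C2",
    "AB1",
    "AB2",
    "B1C1",
    "B2C1",
    "B1C2",
    "B2C2",
)

#: Column indices of each testable term group (main effects and interactions).
TERM_GROUPS: dict[str, tuple[int, ...]] = {
    "A": (1,),
    "B": (2, 3),
    "C": (4, 5),
    "AB": (6, 7),
    "BC": (8, 9, 10, 11),
}

_POLYMER_ALIASES = {
    "kollicoat protect": "Kollicoat Protect",
    "kollicoatprotect": "Kollicoat Protect",
    "kollicoat": "Kollicoat Protect",
    "kollidon va64": "Kollidon VA64",
    "kollidonva64": "Kollidon VA64",
    "kollidon": "Kollidon VA64",
}

# Two-column contrast codes for the three-level factors, in domain order.
_CONTRAST3 = ((1.0, 0.0), (0.0, 1.0), (-1.0, -1.0))


class FactorLevels(NamedTuple):
    """One coating condition: polymer, concentration (% w/v), ratio (mL/g)."""

    polymer: str
    concentration_pct: float
    ratio: str

    def canonical(self) -> "FactorLevels":
        return FactorLevels(
            _canonical_polymer(self.polymer),
            _canonical_concentration(self.concentration_pct),
            _canonical_ratio(self.ratio),
        )


def _canonical_polymer(value: str) -> str:
    key = str(value).replace("®", "").strip().lower()
    if key not in _POLYMER_ALIASES:
        raise ValueError(
            f"unknown polymer level {value!r}; expected one of {POLYMERS}"
        )
    return _POLYMER_ALIASES[key]


def _canonical_concentration(value: float) -> float:
    for level in CONCENTRATIONS:
        if math.isclose(float(value), level, rel_tol=0.0, abs_tol=1e-9):
            return level
    raise ValueError(
        f"unknown concentration level {value!r}; expected one of {CONCENTRATIONS}"
    )


def _canonical_ratio(value) -> str:
    text = str(value).strip()
    if text in RATIOS:
        return text
    try:
        numeric = float(text)
    except ValueError:
        numeric = None
    if numeric is not None:
        for ratio in RATIOS:
            if math.isclose(numeric, float(ratio.split(":")[0])):
                return ratio
    raise ValueError(f"unknown ratio level {value!r}; expected one of {RATIOS}")


def load_coating_design() -> pd.DataFrame:
    """Load the packaged 20-run coating design table.

    Columns: ``run_id, polymer, concentration_pct, ratio,
    coated_surface_pct``.
    """
    with resources.files("pelletcoat.data").joinpath("coating_design.csv").open() as fh:
        table = pd.read_csv(fh)
    return validate_design_table(table)


def validate_design_table(table: pd.DataFrame, require_response: bool = True) -> pd.DataFrame:
    """Canonicalise factor levels and check the design-table contract."""
    required = ["run_id", "polymer", "concentration_pct", "ratio"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"design table missing columns {missing}")
    out = table.copy()
    out["polymer"] = out["polymer"].map(_canonical_polymer)
    out["concentration_pct"] = out["concentration_pct"].map(_canonical_concentration)
    out["ratio"] = out["ratio"].map(_canonical_ratio)
    if out["run_id"].duplicated().any():
        dupes = out.loc[out["run_id"].duplicated(), "run_id"].tolist()
        raise ValueError(f"duplicate run_id values: {dupes}")
    if require_response:
        if "coated_surface_pct" not in out.columns:
            raise ValueError("design table missing column 'coated_surface_pct'")
        y = out["coated_surface_pct"].to_numpy(float)
        if np.any(~np.isfinite(y)) or np.any(y < 0) or np.any(y > 100):
            raise ValueError("responses must be finite percentages in [0, 100]")
    return out


def encode_run(levels: FactorLevels | Sequence) -> np.ndarray:
    """Contrast-code one run as the vector ``(A, B1, B2, C1, C2)``.

    A is -1 for Kollicoat Protect and +1 for Kollidon VA64; the
    three-level factors map level 1 -> (1, 0), level 2 -> (0, 1) and
    level 3 -> (-1, -1) in domain order.
    """
    levels = FactorLevels(*levels).canonical()
    a = -1.0 if levels.polymer == "Kollicoat Protect" else 1.0
    b1, b2 = _CONTRAST3[CONCENTRATIONS.index(levels.concentration_pct)]
    c1, c2 = _CONTRAST3[RATIOS.index(levels.ratio)]
    return np.array([a, b1, b2, c1, c2])


def _model_row(coded: np.ndarray) -> np.ndarray:
    a, b1, b2, c1, c2 = coded
    return np.array(
        [1.0, a, b1, b2, c1, c2,
         a * b1, a * b2,
         b1 * c1, b2 * c1, b1 * c2, b2 * c2]
    )


def build_design_matrix(table: pd.DataFrame) -> np.ndarray:
    """Expand a design table into the 12-column model matrix.

    Column order: intercept, A, B1, B2, C1, C2, AB1, AB2, B1C1, B2C1,
    B1C2, B2C2.  Raises if the run set leaves the matrix rank-deficient,
    reporting which columns are aliased.
    """
    table = validate_design_table(table, require_response=False)
    rows = [
        _model_row(encode_run(FactorLevels(p, c, r)))
        for p, c, r in zip(table["polymer"], table["concentration_pct"], table["ratio"])
    ]
    X = np.vstack(rows)
    if X.shape[0] >= X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X)
        raise ValueError(
            f"design matrix is rank deficient; aliased columns: {aliased}"
        )
    return X


def _aliased_columns(X: np.ndarray) -> list[str]:
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(X[:, trial]) < len(trial):
            aliased.append(TERM_NAMES[j])
        else:
            kept.append(j)
    return aliased


@dataclass
class AnovaRow:
    term: str
    df: int
    sum_sq: float
    f_value: float
    p_value: float


@dataclass
class CodedModel:
    """A fitted coated-surface model on the categorical contrast coding."""

    coefficients: dict[str, float]
    X: np.ndarray
    y: np.ndarray
    residuals: np.ndarray
    hat_diagonals: np.ndarray
    sse: float
    sst: float
    table: pd.DataFrame | None = None
    _anova: list[AnovaRow] | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in TERM_NAMES])

    @classmethod
    def from_coefficients(cls, coefficients: Mapping[str, float]) -> "CodedModel":
        """Build a prediction-only model from explicit term coefficients.

        Missing terms default to zero; useful for evaluating a published
        coefficient set without refitting.
        """
        unknown = set(coefficients) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        coefs = {t: float(coefficients.get(t, 0.0)) for t in TERM_NAMES}
        empty = np.zeros((0, len(TERM_NAMES)))
        return cls(coefs, empty, np.zeros(0), np.zeros(0), np.zeros(0), 0.0, 0.0)

    def to_dict(self) -> dict:
        out = {
            "coefficients": self.coefficients,
            "n_runs": self.n,
            "n_parameters": self.p,
        }
        if self.n:
            r2, adj, pred, press = r_squared_suite(self)
            out.update(
                {"r2": r2, "adj_r2": adj, "pred_r2": pred, "press": press,
                 "anova": [vars(row) for row in anova(self)]}
            )
        return out


def fit_model(table: pd.DataFrame) -> CodedModel:
    """Fit the coded-factor model to a design table by least squares."""
    table = validate_design_table(table)
    if len(table) <= len(TERM_NAMES):
        raise ValueError(
            f"underdetermined fit: {len(table)} runs for {len(TERM_NAMES)} parameters"
        )
    X = build_design_matrix(table)
    y = table["coated_surface_pct"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    residuals = y - fitted
    # hat diagonals via the thin QR factor: h_ii = ||q_i||^2
    q, _ = np.linalg.qr(X)
    hat = np.einsum("ij,ij->i", q, q)
    sse = float(residuals @ residuals)
    sst = float(((y - y.mean()) ** 2).sum())
    coefs = dict(zip(TERM_NAMES, map(float, beta)))
    return CodedModel(coefs, X, y, residuals, hat, sse, sst, table=table)


def _sse_of(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova(model: CodedModel) -> list[AnovaRow]:
    """Partial (Type III) F-tests for each term group, plus the overall model.

    Each group (A, B, C, AB, BC) is tested by the extra sum of squares of
    the full model against the model with that group's columns removed.
    With zero residual variance (an exact fit), p is reported as 0.0 for
    groups with positive extra SS and 1.0 otherwise.
    """
    if model.n == 0:
        raise ValueError("cannot run ANOVA on a coefficients-only model")
    if model.df_resid < 1:
        raise ValueError("ANOVA requires at least one residual degree of freedom")
    if model._anova is not None:
        return model._anova
    mse = model.sse / model.df_resid
    exact_fit = mse <= 1e-12 * max(1.0, model.sst)
    rows: list[AnovaRow] = []
    for name, cols in TERM_GROUPS.items():
        keep = [j for j in range(model.p) if j not in cols]
        extra = _sse_of(model.X[:, keep], model.y) - model.sse
        df = len(cols)
        if exact_fit:
            f_val, p_val = (math.inf, 0.0) if extra > 1e-10 else (0.0, 1.0)
        else:
            f_val = (extra / df) / mse
            p_val = float(stats.f.sf(f_val, df, model.df_resid))
        rows.append(AnovaRow(name, df, float(extra), float(f_val), p_val))
    ss_model = model.sst - model.sse
    df_model = model.p - 1
    if exact_fit:
        rows.append(AnovaRow("model", df_model, float(ss_model), math.inf, 0.0))
    else:
        f_val = (ss_model / df_model) / mse
        rows.append(
            AnovaRow("model", df_model, float(ss_model), float(f_val),
                     float(stats.f.sf(f_val, df_model, model.df_resid)))
        )
    model._anova = rows
    return rows


def r_squared_suite(model: CodedModel) -> tuple[float, float, float, float]:
    """Return ``(r2, adj_r2, pred_r2, press)`` for a fitted model.

    PRESS is computed from the hat diagonals,
    ``PRESS = sum((e_i / (1 - h_ii))**2)``, equivalent to n explicit
    leave-one-out refits.
    """
    if model.n == 0:
        raise ValueError("R² suite requires a fitted model")
    leverage_one = np.isclose(model.hat_diagonals, 1.0, atol=1e-10)
    if leverage_one.any():
        runs = np.flatnonzero(leverage_one) + 1
        raise ValueError(
            f"PRESS undefined: run(s) {runs.tolist()} have leverage h_ii = 1 "
            "(the run cannot be predicted when left out)"
        )
    r2 = 1.0 - model.sse / model.sst
    adj = 1.0 - (model.sse / model.df_resid) / (model.sst / (model.n - 1))
    press = float(((model.residuals / (1.0 - model.hat_diagonals)) ** 2).sum())
    pred = 1.0 - press / model.sst
    return r2, adj, pred, press


def predict(model: CodedModel, levels: FactorLevels | Sequence) -> float:
    """Predicted coated surface (%) at one factor-level combination."""
    return float(_model_row(encode_run(levels)) @ model.beta)


def full_factorial() -> list[FactorLevels]:
    """All 18 combinations of the factor domain."""
    return [
        FactorLevels(p, c, r)
        for p in POLYMERS
        for c in CONCENTRATIONS
        for r in RATIOS
    ]


def optimize(
    model: CodedModel,
    threshold_pct: float = 90.0,
    tie_band_pct: float = 7.5,
    tie_break: bool = True,
) -> pd.DataFrame:
    """Rank coating conditions whose predicted coverage meets a threshold.

    All 18 factor-level combinations are evaluated; those predicting at
    least ``threshold_pct`` coverage are returned sorted by predicted
    coverage, descending.  With ``tie_break`` enabled, conditions whose
    predictions fall within ``tie_band_pct`` points of the current group
    leader are treated as operationally equivalent and reordered by
    process cost: lower suspension-to-pellets ratio first, then lower
    polymer concentration.  The default band of 7.5 points spans the gap
    between the best 3:1 and 2:1 conditions, which deliver practically
    the same coverage at different coating times.
    """
    records = []
    for levels in full_factorial():
        records.append(
            {
                "polymer": levels.polymer,
                "concentration_pct": levels.concentration_pct,
                "ratio": levels.ratio,
                "predicted_pct": predict(model, levels),
            }
        )
    grid = pd.DataFrame(records)
    selected = grid[grid["predicted_pct"] >= threshold_pct].copy()
    selected.sort_values("predicted_pct", ascending=False, inplace=True,
                         kind="mergesort")
    selected.reset_index(drop=True, inplace=True)
    if not tie_break or selected.empty:
        return selected
    # group rows within tie_band_pct of each group's leader, then order
    # each group by cost (ratio ascending, concentration ascending)
    ordered: list[pd.DataFrame] = []
    remaining = selected
    while not remaining.empty:
        leader = remaining["predicted_pct"].iloc[0]
        in_band = remaining["predicted_pct"] >= leader - tie_band_pct
        group = remaining[in_band].copy()
        group["_ratio_key"] = group["ratio"].map(lambda r: int(r.split(":")[0]))
        group.sort_values(
            ["_ratio_key", "concentration_pct", "predicted_pct"],
            ascending=[True, True, False],
            inplace=True,
            kind="mergesort",
        )
        ordered.append(group.drop(columns="_ratio_key"))
        remaining = remaining[~in_band]
    return pd.concat(ordered, ignore_index=True)
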