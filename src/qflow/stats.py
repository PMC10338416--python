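"""Group-level statistics: factorial model, LS-means contrasts, effect sizes.

Each subject contributes one response per cell type and receptor (the median
or IQR of their receptor distribution).  Right-skewed responses (Shapiro-Wilk
p < 0.05 and skewness > 1.5) are log10-transformed.  A factorial ordinary
least squares model with the three subject factors (sex, race, age category)
and their two-way interactions provides least-squares means; sex-by-age cell
contrasts are reported with t-based confidence intervals and Cohen's d,
standardized by the model's residual standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .errors import InvalidArgumentError, MissingCellError

SKEWNESS_GATE = 1.5
NORMALITY_ALPHA = 0.05

_FULL_TERMS = [
    "C(sex)",
    "C(race)",
    "C(age_category)",
    "C(sex):C(age_category)",
    "C(sex):C(race)",
    "C(race):C(age_category)",
]
# interactions sacrificed first when the design is rank deficient
_DROP_ORDER = ["C(race):C(age_category)", "C(sex):C(race)"]


@dataclass(frozen=True)
class SampleSummary:
    """One subject's response for one cell type x receptor."""

    subject_id: str
    group: str
    response: float  # median or IQR, receptors/cell
    sex: str
    race: str
    age_category: str  # under50 | over50
    response_log: float | None = None

    def __post_init__(self) -> None:
        if self.response_log is not None and self.response <= 0:
            raise InvalidArgumentError("log response requires a positive response")


@dataclass(frozen=True)
class GroupComparison:
    """An LS-means contrast between two sex-by-age cells."""

    cell_a: tuple[str, str]
    cell_b: tuple[str, str]
    estimate: float  # difference of LS-means (log scale when transformed)
    ci_low: float
    ci_high: float
    p_value: float
    cohens_d: float  # |estimate| / residual SD

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise InvalidArgumentError("estimate must lie inside its CI")


@dataclass
class TransformResult:
    values: np.ndarray
    transform_applied: bool
    shapiro_p: float
    skewness: float
    degenerate: bool = False


def check_and_transform(values) -> TransformResult:
    """Shapiro-Wilk + skewness-gated log10 transform.

    The transform applies only when the sample is both non-normal at the 5%
    level and right-skewed with skewness > 1.5.  A constant sequence is
    degenerate for Shapiro-Wilk and is returned untransformed with a flag.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InvalidArgumentError("need at least 3 values")
    if np.ptp(values) == 0:
        return TransformResult(values, False, np.nan, 0.0, degenerate=True)
    shapiro_p = float(sps.shapiro(values).pvalue)
    skewness = float(sps.skew(values, bias=False))
    if shapiro_p < NORMALITY_ALPHA and skewness > SKEWNESS_GATE:
        if np.any(values <= 0):
            raise InvalidArgumentError("log transform requires positive values")
        return TransformResult(np.log10(values), True, shapiro_p, skewness)
    return TransformResult(values, False, shapiro_p, skewness)


@dataclass
class FactorialModel:
    """Fitted factorial OLS plus the metadata needed for LS-means."""

    result: object  # statsmodels RegressionResults
    data: pd.DataFrame
    terms: list[str]
    dropped_terms: list[str]

    @property
    def residual_ms(self) -> float:
        return float(self.result.mse_resid)

    @property
    def residual_df(self) -> float:
        return float(self.result.df_resid)


def summaries_to_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in summaries],
            "group": [s.group for s in summaries],
            "sex": [s.sex for s in summaries],
            "race": [s.race for s in summaries],
            "age_category": [s.age_category for s in summaries],
            "response": [
                s.response_log if s.response_log is not None else s.response
                for s in summaries
            ],
        }
    )
    return df


def factorial_fit(summaries: list[SampleSummary]) -> FactorialModel:
    """OLS of the (possibly transformed) response on the factorial design.

    Factors with a single observed level are dropped with a warning, as are
    interactions that make the design rank deficient (race interactions are
    sacrificed first; the sex-by-age interaction, which carries the contrasts
    of interest, is kept whenever possible).
    """
    df = summaries_to_frame(summaries)
    dropped: list[str] = []

    factors = {"C(sex)": "sex", "C(race)": "race", "C(age_category)": "age_category"}
    terms = list(_FULL_TERMS)
    for term, col in factors.items():
        if df[col].nunique() < 2:
            warnings.warn(f"factor {col!r} has a single level; dropping it", stacklevel=2)
            dropped.extend(t for t in terms if col in t)
            terms = [t for t in terms if col not in t]

    drop_queue = [t for t in _DROP_ORDER if t in terms]
    while True:
        formula = "response ~ " + " + ".join(terms) if terms else "response ~ 1"
        model = smf.ols(formula, data=df)
        rank = np.linalg.matrix_rank(model.exog)
        if rank == model.exog.shape[1] or not drop_queue:
            break
        term = drop_queue.pop(0)
        warnings.warn(
            f"rank-deficient design; dropping term {term}", stacklevel=2
        )
        dropped.append(term)
        terms = [t for t in terms if t != term]

    result = model.fit()
    return FactorialModel(result=result, data=df, terms=terms, dropped_terms=dropped)


def _lsmean_row(model: FactorialModel, sex: str, age: str) -> np.ndarray:
    """Design-space representation of a sex-by-age LS-mean.

    Predictions are averaged over the observed race levels with equal
    weights, matching the least-squares-means convention for unbalanced data.
    """
    races = sorted(model.data["race"].unique())
    grid = pd.DataFrame(
        {"sex": sex, "age_category": age, "race": races, "response": 0.0}
    )
    (exog,) = build_design_matrices([model.result.model.data.design_info], grid)
    return np.asarray(exog).mean(axis=0)


def lsmeans_contrast(
    model: FactorialModel,
    cell_a: tuple[str, str],
    cell_b: tuple[str, str],
    alpha: float = 0.05,
) -> GroupComparison:
    """LS-mean difference between two (sex, age_category) cells.

    The contrast's standard error uses the model covariance and residual
    degrees of freedom (t distribution); Cohen's d is the absolute contrast
    divided by the residual standard deviation.
    """
    for sex, age in (cell_a, cell_b):
        observed = model.data[
            (model.data["sex"] == sex) & (model.data["age_category"] == age)
        ]
        if observed.empty:
            raise MissingCellError(f"no observations in cell ({sex}, {age})")

    contrast = _lsmean_row(model, *cell_a) - _lsmean_row(model, *cell_b)
    test = model.result.t_test(contrast)
    estimate = float(np.atleast_1d(test.effect)[0])
    ci_low, ci_high = (float(v) for v in np.atleast_2d(test.conf_int(alpha))[0])
    p_value = float(np.atleast_1d(test.pvalue)[0])
    rms = model.residual_ms
    cohens_d = abs(estimate) / np.sqrt(rms) if rms > 0 else (0.0 if estimate == 0 else np.inf)
    return GroupComparison(
        cell_a=cell_a,
        cell_b=cell_b,
        estimate=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        cohens_d=float(cohens_d),
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Optional Holm step-down adjustment for users running many contrasts."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (len(p) - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()
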