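"""Scale scoring, reliability, the disruption composite, residualization,
and the attrition (loss-to-follow-up) comparison.

All scoring is strict complete-case: a person missing any item of a scale
gets a missing score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

TIMINGS = ("past_year", "previously", "none")


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    item_names: tuple[str, ...]
    response_min: int
    response_max: int
    reverse_items: tuple[str, ...] = ()
    scoring: str = "sum"

    def __post_init__(self):
        if self.response_min >= self.response_max:
            raise ValidationError("response_min must be < response_max")
        bad = set(self.reverse_items) - set(self.item_names)
        if bad:
            raise ValidationError(f"reverse_items not in item_names: {sorted(bad)}")
        if self.scoring not in ("sum", "mean"):
            raise ValidationError("scoring must be 'sum' or 'mean'")

    @property
    def n_items(self) -> int:
        return len(self.item_names)


def default_scale_definitions() -> dict[str, ScaleDefinition]:
    """Scale definitions shipped with the package (see data/scales.yaml)."""
    text = resources.files("twinwell").joinpath("data/scales.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, d in raw.items():
        out[name] = ScaleDefinition(
            name=name,
            item_names=tuple(d["items"]),
            response_min=int(d["response_min"]),
            response_max=int(d["response_max"]),
            reverse_items=tuple(d.get("reverse_items", [])),
            scoring=d.get("scoring", "sum"),
        )
    return out


def reverse_code(x, response_min: int, response_max: int):
    """Map x -> min + max - x (an involution on the response range)."""
    return response_min + response_max - np.asarray(x, dtype=float)


def score_scale(items, definition: ScaleDefinition):
    """Score a scale from item responses.

    Parameters
    ----------
    items:
        Either a mapping item_name -> response (one person) or a DataFrame
        with one row per person and the scale's items as columns.

    Returns
    -------
    float (or NaN) for a single person; a pandas Series for a DataFrame.
    """
    if isinstance(items, Mapping):
        frame = pd.DataFrame([items])
        single = True
    else:
        frame = items
        single = False
    missing_cols = [c for c in definition.item_names if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"missing item column(s): {missing_cols}")

    mat = frame[list(definition.item_names)].to_numpy(dtype=float)
    observed = ~np.isnan(mat)
    out_of_range = observed & (
        (mat < definition.response_min) | (mat > definition.response_max)
    )
    if out_of_range.any():
        i, j = np.argwhere(out_of_range)[0]
        raise ValidationError(
            f"response {mat[i, j]} out of range "
            f"[{definition.response_min}, {definition.response_max}] "
            f"for item {definition.item_names[j]!r}"
        )
    for k, item in enumerate(definition.item_names):
        if item in definition.reverse_items:
            mat[:, k] = reverse_code(
                mat[:, k], definition.response_min, definition.response_max
            )
    complete = observed.all(axis=1)
    scores = np.full(len(mat), np.nan)
    if definition.scoring == "sum":
        scores[complete] = mat[complete].sum(axis=1)
    else:
        scores[complete] = mat[complete].mean(axis=1)
    if single:
        return float(scores[0]) if complete[0] else float("nan")
    return pd.Series(scores, index=frame.index, name=definition.name)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(var_i) / var_total).

    Uses unbiased (n-1) variances on complete-case rows only.
    """
    mat = np.asarray(pd.DataFrame(item_matrix), dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise UndefinedStatisticError("alpha requires at least 2 items")
    mat = mat[~np.isnan(mat).any(axis=1)]
    if mat.shape[0] < 3:
        raise UndefinedStatisticError("alpha requires at least 3 complete rows")
    k = mat.shape[1]
    item_vars = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass(frozen=True)
class DisruptionRecord:
    """Timing of three stressful interpersonal events."""

    divorce_or_separation: str = "none"
    partner_conflict: str = "none"
    other_conflict: str = "none"

    def __post_init__(self):
        for f in ("divorce_or_separation", "partner_conflict", "other_conflict"):
            v = getattr(self, f)
            if v not in TIMINGS:
                raise ValidationError(f"{f}={v!r} not in {TIMINGS}")

    @property
    def timings(self) -> tuple[str, str, str]:
        return (self.divorce_or_separation, self.partner_conflict, self.other_conflict)


def disruption_composite(rec: DisruptionRecord) -> dict[str, int]:
    """0/1 composite: any event; any past-year event; any previous event."""
    t = rec.timings
    return {
        "overall": int(any(x != "none" for x in t)),
        "past_year": int(any(x == "past_year" for x in t)),
        "previous": int(any(x == "previously" for x in t)),
    }


def residualize(y, age, sex) -> np.ndarray:
    """OLS residuals of y on intercept + age + sex indicator (F=0, M=1).

    Residuals have mean zero and are orthogonal to the regressors.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in ("U", "S", "O"):
        sex_num = np.where(sex == "M", 1.0, 0.0)
        bad = ~np.isin(sex, ("F", "M"))
        if bad.any():
            raise ValidationError(f"unknown sex code(s): {set(sex[bad])}")
    else:
        sex_num = sex.astype(float)
    if np.isnan(age).any() or np.isnan(sex_num).any():
        raise ValidationError("regressors must be complete for retained rows")
    X = np.column_stack([np.ones_like(age), age, sex_num])
    keep = ~np.isnan(y)
    resid = np.full_like(y, np.nan)
    if keep.sum() == 0:
        return resid
    beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    resid[keep] = y[keep] - X[keep] @ beta
    return resid


def attrition_compare(scores_retained, scores_lost) -> dict[str, float]:
    """Group means and Welch two-sample test (retained vs lost to follow-up)."""
    a = np.asarray(scores_retained, dtype=float)
    b = np.asarray(scores_lost, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_retained": float(a.mean()),
        "mean_lost": float(b.mean()),
        "t": float(t),
        "p": float(p),
        "n_retained": int(len(a)),
        "n_lost": int(len(b)),
    }
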