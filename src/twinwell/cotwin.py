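"""Co-twin control analyses.

Full-sample model: wellbeing on exposure + sex + age with a random intercept
per twin pair. MZ-only model: the exposure is split into a between-pair
component (the pair mean) and a within-pair component (individual minus pair
mean); the within coefficient is free of all confounders the twins share.

The random-intercept Gaussian model is estimated by profiling the variance
ratio lambda = tau^2 / sigma^2: for clusters of size <= 2 the GLS fixed
effects and the residual variance are closed-form given lambda, so only a
one-dimensional optimization remains. REML is the default; ML is available
for likelihood comparisons against brute-force oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DegenerateDesignError, FitError, ValidationError
from .twin_data import TwinDataset

Z975 = 1.959963984540054

EFFECT_BANDS = ((0.30, "large"), (0.20, "medium"), (0.10, "small"), (0.05, "very_small"))


@dataclass(frozen=True)
class CoTwinSpec:
    exposure: str
    outcome: str
    covariates: tuple[str, ...] = ("sex", "age")
    sample: str = "full"                 # "full" | "MZ_only"
    standardize_outcome: bool = True
    standardize_exposure: bool = True    # False for 0/1 disruption variables
    reml: bool = True

    def __post_init__(self):
        if self.exposure == self.outcome:
            raise ValidationError("exposure and outcome must differ")
        if self.sample not in ("full", "MZ_only"):
            raise ValidationError("sample must be 'full' or 'MZ_only'")


@dataclass
class CoTwinFit:
    spec: CoTwinSpec
    beta0: float
    beta_within: float | None
    beta_between: float | None
    beta_full: float | None
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    tau2: float
    sigma2: float
    n_individuals: int
    n_pairs: int
    n_excluded_singletons: int
    effect_label: str
    boundary: bool
    reml: bool
    coefficients: dict[str, float] = field(default_factory=dict)

    @property
    def primary_beta(self) -> float:
        return self.beta_within if self.spec.sample == "MZ_only" else self.beta_full

    @property
    def primary_ci(self) -> tuple[float, float]:
        key = "within" if self.spec.sample == "MZ_only" else "exposure"
        return self.ci[key]

    def to_dict(self) -> dict:
        return {
            "exposure": self.spec.exposure,
            "outcome": self.spec.outcome,
            "sample": self.spec.sample,
            "beta0": self.beta0,
            "beta_within": self.beta_within,
            "beta_between": self.beta_between,
            "beta_full": self.beta_full,
            "se": self.se,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "n_individuals": self.n_individuals,
            "n_pairs": self.n_pairs,
            "effect_label": self.effect_label,
            "boundary": self.boundary,
            "reml": self.reml,
        }


def decompose(values, pair_ids) -> tuple[np.ndarray, np.ndarray]:
    """Split values into within-pair deviations and between-pair means.

    within = x_ij - mean_i(x); between = mean_i(x). The within component sums
    to zero inside every pair; the between component is pair-constant.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    pid = pd.Series(np.asarray(pair_ids))
    means = s.groupby(pid.values).transform("mean")
    return (s - means).to_numpy(), means.to_numpy()


def classify_effect(r: float) -> str:
    """Label a standardized coefficient magnitude against fixed bands."""
    a = abs(float(r))
    for cut, label in EFFECT_BANDS:
        if a >= cut:
            return label
    return "negligible"


# ---------------------------------------------------------------------------
# random-intercept model, profiled over lambda = tau^2 / sigma^2
# ---------------------------------------------------------------------------

def _gls_profile(X, y, cluster_sizes, cluster_starts, lam, reml):
    """GLS at fixed lambda. Returns (crit, beta, cov_unit, rss, n, p, logdetV)."""
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdetV = 0.0
    # V_i = I + lam * J; V_i^-1 = I - (lam / (1 + k*lam)) * J
    for size in (1, 2):
        sel = cluster_sizes == size
        if not sel.any():
            continue
        starts = cluster_starts[sel]
        if size == 1:
            Xi = X[starts]
            yi = y[starts]
            w = 1.0 / (1.0 + lam)
            XtVX += w * Xi.T @ Xi
            XtVy += w * Xi.T @ yi
            logdetV += len(starts) * math.log1p(lam)
        else:
            idx = np.stack([starts, starts + 1], axis=1)  # (nc, 2)
            Xi = X[idx]                                   # (nc, 2, p)
            yi = y[idx]                                   # (nc, 2)
            c = lam / (1.0 + 2.0 * lam)
            rowsum_X = Xi.sum(axis=1)                     # (nc, p)
            rowsum_y = yi.sum(axis=1)                     # (nc,)
            XtVX += np.einsum("nkp,nkq->pq", Xi, Xi) - c * rowsum_X.T @ rowsum_X
            XtVy += np.einsum("nkp,nk->p", Xi, yi) - c * rowsum_X.T @ rowsum_y
            logdetV += len(starts) * math.log1p(2.0 * lam)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError(f"singular design: {exc}") from exc
    r = y - X @ beta
    rss = 0.0
    for size in (1, 2):
        sel = cluster_sizes == size
        if not sel.any():
            continue
        starts = cluster_starts[sel]
        if size == 1:
            rss += (r[starts] ** 2).sum() / (1.0 + lam)
        else:
            ri = np.stack([r[starts], r[starts + 1]], axis=1)
            c = lam / (1.0 + 2.0 * lam)
            rss += (ri**2).sum() - c * (ri.sum(axis=1) ** 2).sum()
    dof = n - p if reml else n
    sigma2 = rss / dof
    crit = dof * math.log(sigma2) + logdetV
    if reml:
        sign, logdetA = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise DegenerateDesignError("X'V^-1X not positive definite")
        crit += logdetA
    return crit, beta, np.linalg.inv(XtVX), rss, sigma2


def _fit_random_intercept(X, y, pair_ids, reml=True):
    """Profile-likelihood fit. Data must be sorted so clusters are contiguous."""
    order = np.argsort(pair_ids, kind="stable")
    X, y, pair_ids = X[order], y[order], np.asarray(pair_ids)[order]
    ids, starts, counts = np.unique(pair_ids, return_index=True, return_counts=True)
    if counts.max() > 2:
        raise ValidationError("clusters larger than 2 are not supported")

    def crit_of(u):
        lam = math.exp(u)
        try:
            return _gls_profile(X, y, counts, starts, lam, reml)[0]
        except DegenerateDesignError:
            return np.inf

    res = optimize.minimize_scalar(crit_of, bounds=(-14.0, 8.0), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise FitError("variance-ratio optimization failed", diagnostics={"result": str(res)})
    crit0 = _gls_profile(X, y, counts, starts, 0.0, reml)[0]
    boundary = crit0 <= res.fun + 1e-10
    lam = 0.0 if boundary else math.exp(res.x)
    crit, beta, cov_unit, rss, sigma2 = _gls_profile(X, y, counts, starts, lam, reml)
    tau2 = lam * sigma2
    cov_beta = sigma2 * cov_unit
    return {
        "beta": beta,
        "cov_beta": cov_beta,
        "tau2": tau2,
        "sigma2": sigma2,
        "lambda": lam,
        "boundary": boundary,
        "criterion": crit,
        "n": len(y),
        "n_clusters": len(ids),
    }


def minus2_loglik_ml(X, y, pair_ids, beta, tau2, sigma2) -> float:
    """Exact -2 log likelihood of the random-intercept model (for oracles)."""
    order = np.argsort(np.asarray(pair_ids), kind="stable")
    X, y, pair_ids = X[order], y[order], np.asarray(pair_ids)[order]
    r = y - X @ beta
    total = 0.0
    for pid in np.unique(pair_ids):
        sel = pair_ids == pid
        k = sel.sum()
        V = sigma2 * np.eye(k) + tau2 * np.ones((k, k))
        ri = r[sel]
        sign, logdet = np.linalg.slogdet(V)
        total += k * math.log(2 * math.pi) + logdet + ri @ np.linalg.solve(V, ri)
    return float(total)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateDesignError("cannot standardize a constant variable")
    return (x - np.nanmean(x)) / sd


def fit_mixed(spec: CoTwinSpec, ds: TwinDataset) -> CoTwinFit:
    """Fit the co-twin control mixed model for one exposure/outcome."""
    needed = [spec.outcome, spec.exposure, *spec.covariates]
    df = ds.df[["pair_id", "twin_index", "zygosity", "sex", "age", *[
        c for c in needed if c not in ("sex", "age")
    ]]].copy()
    if spec.sample == "MZ_only":
        df = df[df["zygosity"] == "MZ"]
    model_cols = [spec.outcome, spec.exposure] + [c for c in spec.covariates]
    df["sex_num"] = (df["sex"] == "M").astype(float)
    use_cols = [c if c != "sex" else "sex_num" for c in model_cols]
    df = df.dropna(subset=use_cols)

    n_singletons_excluded = 0
    if spec.sample == "MZ_only":
        sizes = df.groupby("pair_id")["twin_index"].transform("size")
        n_singletons_excluded = int((sizes == 1).sum())
        df = df[sizes == 2]
    if len(df) < 4:
        raise FitError(f"too few complete cases: {len(df)}")

    y = df[spec.outcome].to_numpy(dtype=float)
    x = df[spec.exposure].to_numpy(dtype=float)
    if spec.standardize_outcome:
        y = _zscore(y)
    if spec.standardize_exposure:
        x = _zscore(x)

    cov_mat = []
    cov_names = []
    for c in spec.covariates:
        col = df["sex_num"].to_numpy() if c == "sex" else df[c].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            continue  # constant covariate (e.g. single-sex sample): drop, not error
        cov_names.append(c)
        cov_mat.append(col)

    pair_ids = df["pair_id"].to_numpy()
    if spec.sample == "MZ_only":
        within, between = decompose(x, pair_ids)
        if np.allclose(within, 0):
            raise DegenerateDesignError(
                "no within-pair variance in exposure: beta_within is unidentified"
            )
        X = np.column_stack([np.ones(len(y)), within, between, *cov_mat])
        names = ["intercept", "within", "between", *cov_names]
    else:
        X = np.column_stack([np.ones(len(y)), x, *cov_mat])
        names = ["intercept", "exposure", *cov_names]

    res = _fit_random_intercept(X, y, pair_ids, reml=spec.reml)
    beta = dict(zip(names, res["beta"]))
    se = {nm: float(np.sqrt(res["cov_beta"][i, i])) for i, nm in enumerate(names)}
    ci = {nm: (beta[nm] - Z975 * se[nm], beta[nm] + Z975 * se[nm]) for nm in names}

    if spec.sample == "MZ_only":
        primary = beta["within"]
    else:
        primary = beta["exposure"]

    return CoTwinFit(
        spec=spec,
        beta0=float(beta["intercept"]),
        beta_within=float(beta["within"]) if "within" in beta else None,
        beta_between=float(beta["between"]) if "between" in beta else None,
        beta_full=float(beta["exposure"]) if "exposure" in beta else None,
        se=se,
        ci={k: (float(a), float(b)) for k, (a, b) in ci.items()},
        tau2=float(res["tau2"]),
        sigma2=float(res["sigma2"]),
        n_individuals=int(res["n"]),
        n_pairs=int(res["n_clusters"]),
        n_excluded_singletons=n_singletons_excluded,
        effect_label=classify_effect(primary),
        boundary=bool(res["boundary"]),
        reml=spec.reml,
        coefficients={k: float(v) for k, v in beta.items()},
    )


# ---------------------------------------------------------------------------
# attenuation summary and panels
# ---------------------------------------------------------------------------

def _beta_and_ci(obj, which):
    if isinstance(obj, CoTwinFit):
        if which == "full":
            return obj.beta_full, obj.ci["exposure"]
        return obj.beta_within, obj.ci["within"]
    beta, ci = obj
    return float(beta), (float(ci[0]), float(ci[1]))


def attenuation_summary(full, mz, *, ratio_threshold: float = 0.8) -> dict:
    """Compare the full-sample and MZ within-pair coefficients.

    Accepts CoTwinFit objects or ``(beta, (ci_lo, ci_hi))`` tuples. Verdicts:
    within CI covering 0 -> fully_attenuated; otherwise ratio >= threshold ->
    no_confounding_indicated, ratio < threshold -> partial_confounding.
    """
    if isinstance(full, CoTwinFit) and isinstance(mz, CoTwinFit):
        if (full.spec.exposure, full.spec.outcome) != (mz.spec.exposure, mz.spec.outcome):
            raise ValidationError("fits must share exposure and outcome")
    beta_full, _ = _beta_and_ci(full, "full")
    beta_w, ci_w = _beta_and_ci(mz, "within")
    if abs(beta_full) < 1e-8:
        ratio = None
    else:
        ratio = beta_w / beta_full
    within_excludes_zero = (ci_w[0] > 0) or (ci_w[1] < 0)
    if not within_excludes_zero:
        verdict = "fully_attenuated"
    elif ratio is not None and ratio >= ratio_threshold:
        verdict = "no_confounding_indicated"
    else:
        verdict = "partial_confounding"
    return {
        "beta_full": beta_full,
        "beta_within": beta_w,
        "within_ci": list(ci_w),
        "ratio": ratio,
        "verdict": verdict,
    }


def run_panel(
    ds: TwinDataset,
    exposures: Sequence[str],
    outcomes: dict[str, str],
    *,
    unstandardized_exposures: Sequence[str] = (),
    reml: bool = True,
) -> pd.DataFrame:
    """Full-sample and MZ within-pair estimates for every exposure x outcome.

    outcomes maps a label (e.g. "concurrent", "lagged") to the outcome trait
    name. Failures are recorded per cell, not raised.
    """
    rows = []
    for label, outcome in outcomes.items():
        for exp in exposures:
            std_x = exp not in unstandardized_exposures
            for sample in ("full", "MZ_only"):
                row = {
                    "exposure": exp,
                    "outcome": label,
                    "sample": "full" if sample == "full" else "mz_within",
                }
                try:
                    spec = CoTwinSpec(
                        exposure=exp, outcome=outcome, sample=sample,
                        standardize_exposure=std_x, reml=reml,
                    )
                    fit = fit_mixed(spec, ds)
                    lo, hi = fit.primary_ci
                    row.update(
                        beta=fit.primary_beta, ci_lo=lo, ci_hi=hi,
                        n_individuals=fit.n_individuals, n_pairs=fit.n_pairs,
                        label=fit.effect_label, error="",
                    )
                except Exception as exc:  # panel completes with failure markers
                    row.update(
                        beta=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                        n_individuals=0, n_pairs=0, label="error",
                        error=f"{type(exc).__name__}: {exc}",
                    )
                rows.append(row)
    cols = ["exposure", "outcome", "sample", "beta", "ci_lo", "ci_hi",
            "n_individuals", "n_pairs", "label", "error"]
    return pd.DataFrame(rows)[cols]


def forest_plot(panel: pd.DataFrame, path) -> None:
    """Plain forest plot of a panel table (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = panel[panel["label"] != "error"].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(ok), 4) + 1.5))
    ypos = np.arange(len(ok))[::-1]
    ax.errorbar(
        ok["beta"], ypos,
        xerr=[ok["beta"] - ok["ci_lo"], ok["ci_hi"] - ok["beta"]],
        fmt="o", capsize=3,
    )
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(
        [f"{r.exposure} / {r.outcome} ({r.sample})" for r in ok.itertuples()]
    )
    ax.set_xlabel("standardized coefficient (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
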