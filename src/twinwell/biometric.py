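"""Multivariate Cholesky twin models (ACE / AE / E).

Each variance component's contribution to the m-trait covariance is
parameterized as L·Lᵀ with L lower-triangular, so the implied covariance is
positive semidefinite by construction. The expected covariance of the
stacked (twin1, twin2) trait vector is

    [[A + C + E,  r·A + C],
     [r·A + C,    A + C + E]]

with r = 1.0 for MZ and 0.5 for DZ pairs. The likelihood is full-information:
each pair contributes the multivariate-normal density of its observed
entries only, so incomplete pairs and incomplete trait vectors are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import ComparabilityError, FitError, ValidationError
from .twin_data import TwinDataset, WidePair, to_wide

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1e12
GENETIC_R = {"MZ": 1.0, "DZ": 0.5}


@dataclass(frozen=True)
class CholeskySpec:
    """Model definition: ordered trait list and included components."""

    traits: tuple[str, ...]
    components: tuple[str, ...] = ("A", "C", "E")

    def __post_init__(self):
        if len(self.traits) < 1:
            raise ValidationError("at least one trait required")
        bad = set(self.components) - {"A", "C", "E"}
        if bad:
            raise ValidationError(f"unknown component(s): {sorted(bad)}")
        if "E" not in self.components:
            raise ValidationError("E must always be included")

    @property
    def m(self) -> int:
        return len(self.traits)

    @property
    def n_free(self) -> int:
        return len(self.components) * self.m * (self.m + 1) // 2

    @property
    def label(self) -> str:
        return "".join(c for c in ("A", "C", "E") if c in self.components)


@dataclass
class CholeskyParams:
    """Lower-triangular path matrices; None for excluded components."""

    L_a: np.ndarray | None = None
    L_c: np.ndarray | None = None
    L_e: np.ndarray | None = None

    def __post_init__(self):
        for name in ("L_a", "L_c", "L_e"):
            L = getattr(self, name)
            if L is not None:
                L = np.asarray(L, dtype=float)
                if L.ndim != 2 or L.shape[0] != L.shape[1]:
                    raise ValidationError(f"{name} must be square")
                if not np.allclose(L, np.tril(L)):
                    raise ValidationError(f"{name} must be lower-triangular")
                setattr(self, name, L)
        if self.L_e is None:
            raise ValidationError("L_e is required")

    @property
    def m(self) -> int:
        return self.L_e.shape[0]

    def component_covariances(self) -> dict[str, np.ndarray]:
        out = {}
        for key, L in (("A", self.L_a), ("C", self.L_c), ("E", self.L_e)):
            out[key] = L @ L.T if L is not None else np.zeros((self.m, self.m))
        return out


def expected_pair_covariance(params: CholeskyParams, zygosity: str) -> np.ndarray:
    """Expected 2m x 2m covariance of the stacked (twin1, twin2) trait vector."""
    if zygosity not in GENETIC_R:
        raise ValidationError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    cov = params.component_covariances()
    A, C, E = cov["A"], cov["C"], cov["E"]
    within = A + C + E
    cross = GENETIC_R[zygosity] * A + C
    return np.block([[within, cross], [cross, within]])


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _tril_indices(m: int):
    return np.tril_indices(m)


def pack_params(params: CholeskyParams, spec: CholeskySpec) -> np.ndarray:
    idx = _tril_indices(spec.m)
    parts = []
    for comp, L in (("A", params.L_a), ("C", params.L_c), ("E", params.L_e)):
        if comp in spec.components:
            parts.append(np.asarray(L)[idx])
    return np.concatenate(parts)


def unpack_params(theta: np.ndarray, spec: CholeskySpec) -> CholeskyParams:
    m = spec.m
    idx = _tril_indices(m)
    step = m * (m + 1) // 2
    mats = {}
    pos = 0
    for comp in ("A", "C", "E"):
        if comp in spec.components:
            L = np.zeros((m, m))
            L[idx] = theta[pos : pos + step]
            mats[comp] = L
            pos += step
    return CholeskyParams(L_a=mats.get("A"), L_c=mats.get("C"), L_e=mats.get("E"))


# ---------------------------------------------------------------------------
# FIML likelihood
# ---------------------------------------------------------------------------

class _PatternGroups:
    """Pairs grouped by (zygosity, missingness pattern) with sufficient stats.

    For a zero-mean model only crossproduct matrices are needed, making each
    likelihood evaluation O(#patterns * m^3) instead of O(#pairs).
    """

    def __init__(self, pairs: Sequence[WidePair], m: int):
        X = np.array([np.concatenate([p.values_twin1, p.values_twin2]) for p in pairs])
        zyg = np.array([p.zygosity for p in pairs])
        self.m = m
        self.groups = []
        obs = ~np.isnan(X)
        keys = {}
        for i in range(len(X)):
            if not obs[i].any():
                continue  # nothing observed: contributes no information
            key = (zyg[i], obs[i].tobytes())
            keys.setdefault(key, []).append(i)
        for (z, maskbytes), idxs in keys.items():
            mask = np.frombuffer(maskbytes, dtype=bool)
            Xg = X[np.asarray(idxs)][:, mask]
            self.groups.append(
                {
                    "zygosity": z,
                    "mask": mask,
                    "n": len(idxs),
                    "S": Xg.T @ Xg,
                    "k": int(mask.sum()),
                }
            )
        self.n_pairs_used = sum(g["n"] for g in self.groups)

    def minus2ll(self, params: CholeskyParams) -> float:
        sigma = {z: expected_pair_covariance(params, z) for z in ("MZ", "DZ")}
        total = 0.0
        for g in self.groups:
            sub = sigma[g["zygosity"]][np.ix_(g["mask"], g["mask"])]
            try:
                cf = linalg.cho_factor(sub, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return _PENALTY
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            quad = np.trace(linalg.cho_solve(cf, g["S"], check_finite=False))
            total += g["n"] * (g["k"] * _LOG2PI + logdet) + quad
        return float(total)

    def minus2ll_vec(self, theta: np.ndarray, spec: CholeskySpec) -> float:
        return self.minus2ll(unpack_params(theta, spec))


def minus2_log_likelihood(
    params: CholeskyParams, pairs: Sequence[WidePair], spec: CholeskySpec | None = None
) -> float:
    """-2 log likelihood of the pairs under a zero-mean FIML normal model.

    Non-positive-definite observed sub-covariances return a large penalty
    (1e12) rather than raising, so optimizers can back off.
    """
    m = params.m
    return _PatternGroups(pairs, m).minus2ll(params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class BiometricFit:
    spec: CholeskySpec
    params: CholeskyParams
    minus2lnL: float
    n_params: int
    AIC: float
    standardized: pd.DataFrame          # per trait: h2, c2, e2
    rg: pd.DataFrame                    # genetic correlations (NaN if undefined)
    re: pd.DataFrame                    # non-shared environmental correlations
    rc: pd.DataFrame | None
    n_pairs: dict[str, int]
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    ci: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.spec.label,
            "traits": list(self.spec.traits),
            "minus2lnL": self.minus2lnL,
            "n_params": self.n_params,
            "AIC": self.AIC,
            "standardized": self.standardized.to_dict(orient="index"),
            "rg": self.rg.values.tolist(),
            "re": self.re.values.tolist(),
            "n_pairs": self.n_pairs,
            "converged": self.converged,
        }
        if self.ci is not None:
            d["ci"] = self.ci
        return d


def _correlation_from_cov(cov: np.ndarray) -> np.ndarray:
    """Correlation matrix; rows/cols with (near-)zero variance become NaN."""
    d = np.diag(cov).copy()
    out = np.full_like(cov, np.nan)
    ok = d > 1e-10
    denom = np.sqrt(np.outer(d[ok], d[ok]))
    out[np.ix_(ok, ok)] = cov[np.ix_(ok, ok)] / denom
    out[np.ix_(ok, ok)] = np.clip(out[np.ix_(ok, ok)], -1.0, 1.0)
    np.fill_diagonal(out, np.where(ok, 1.0, np.nan))
    return out


def standardize(params: CholeskyParams, traits: Sequence[str]):
    """Per-trait (h2, c2, e2) and the rg / rc / re correlation matrices."""
    cov = params.component_covariances()
    total = np.diag(cov["A"] + cov["C"] + cov["E"])
    std = pd.DataFrame(
        {
            "h2": np.diag(cov["A"]) / total,
            "c2": np.diag(cov["C"]) / total,
            "e2": np.diag(cov["E"]) / total,
        },
        index=list(traits),
    )
    rg = pd.DataFrame(_correlation_from_cov(cov["A"]), index=list(traits), columns=list(traits))
    rc = pd.DataFrame(_correlation_from_cov(cov["C"]), index=list(traits), columns=list(traits))
    re = pd.DataFrame(_correlation_from_cov(cov["E"]), index=list(traits), columns=list(traits))
    return std, rg, rc, re


def _prepare_matrix(ds: TwinDataset, traits: Sequence[str], scale: bool) -> TwinDataset:
    """Center (and optionally scale to unit variance) each trait over individuals."""
    df = ds.df.copy()
    for t in traits:
        x = df[t].to_numpy(dtype=float)
        mu = np.nanmean(x)
        sd = np.nanstd(x, ddof=1) if scale else 1.0
        if not np.isfinite(sd) or sd <= 0:
            sd = 1.0
        df[t] = (x - mu) / sd
    return TwinDataset(df, ds.trait_names)


def _start_values(groups: _PatternGroups, pairs, spec: CholeskySpec) -> np.ndarray:
    """Phenotypic-covariance based start: split S_ph equally across components."""
    m = spec.m
    rows = []
    for p in pairs:
        rows.append(p.values_twin1)
        rows.append(p.values_twin2)
    X = np.asarray(rows)
    S = pd.DataFrame(X).cov(min_periods=2).to_numpy()
    if np.isnan(S).any():
        S = np.eye(m)
    S = S + 1e-6 * np.eye(m)
    ncomp = len(spec.components)
    try:
        L0 = np.linalg.cholesky(S / ncomp)
    except np.linalg.LinAlgError:
        L0 = np.sqrt(np.maximum(np.diag(S), 1e-3) / ncomp)[:, None] * np.eye(m)
    p0 = CholeskyParams(
        L_a=L0.copy() if "A" in spec.components else None,
        L_c=L0.copy() if "C" in spec.components else None,
        L_e=L0.copy(),
    )
    return pack_params(p0, spec)


def fit_cholesky(
    ds: TwinDataset,
    spec: CholeskySpec,
    *,
    n_restarts: int = 5,
    perturb_scale: float = 0.2,
    seed: int | None = None,
    standardize_input: bool = True,
    min_pairs: int = 30,
    bootstrap: int = 0,
    tol: float = 1e-8,
) -> BiometricFit:
    """Fit a Cholesky twin model by FIML.

    Input traits are centered (and by default scaled to unit variance), so a
    zero-mean likelihood applies; data should already be residualized on age
    and sex upstream if covariate adjustment is wanted.
    """
    rng = np.random.default_rng(seed)
    traits = list(spec.traits)
    pairs = to_wide(ds, traits)
    counts = {"MZ": 0, "DZ": 0}
    for p in pairs:
        counts[p.zygosity] += 1
    for z, c in counts.items():
        if c < min_pairs:
            raise FitError(
                f"need at least {min_pairs} {z} pairs, got {c}",
                diagnostics={"pair_counts": counts},
            )

    work = _prepare_matrix(ds, traits, scale=standardize_input)
    wpairs = to_wide(work, traits)
    groups = _PatternGroups(wpairs, spec.m)

    theta0 = _start_values(groups, wpairs, spec)
    best = None
    attempts = []
    for r in range(max(1, n_restarts)):
        start = theta0 if r == 0 else theta0 + rng.normal(0, perturb_scale, theta0.shape)
        res = optimize.minimize(
            groups.minus2ll_vec,
            start,
            args=(spec,),
            method="L-BFGS-B",
            options={"ftol": tol * 1e-2, "gtol": 1e-9, "maxiter": 5000, "maxfun": 50000},
        )
        attempts.append({"fun": float(res.fun), "success": bool(res.success)})
        if res.fun < _PENALTY and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= _PENALTY:
        raise FitError("all restarts failed to converge", diagnostics={"attempts": attempts})

    params = unpack_params(best.x, spec)
    m2ll = float(best.fun)
    k = spec.n_free
    std, rg, rc, re = standardize(params, traits)
    fit = BiometricFit(
        spec=spec,
        params=params,
        minus2lnL=m2ll,
        n_params=k,
        AIC=m2ll + 2 * k,
        standardized=std,
        rg=rg,
        re=re,
        rc=rc if "C" in spec.components else None,
        n_pairs=counts,
        converged=bool(best.success),
        diagnostics={"attempts": attempts, "n_pairs_used": groups.n_pairs_used},
    )
    if bootstrap > 0:
        fit.ci = _bootstrap_ci(work, spec, best.x, n_boot=bootstrap, rng=rng, tol=tol)
    return fit


def _bootstrap_ci(work, spec, theta_hat, *, n_boot, rng, tol):
    """Nonparametric bootstrap over pairs, stratified by zygosity."""
    traits = list(spec.traits)
    wpairs = to_wide(work, traits)
    by_z = {"MZ": [p for p in wpairs if p.zygosity == "MZ"],
            "DZ": [p for p in wpairs if p.zygosity == "DZ"]}
    h2_draws, rg_draws = [], []
    for _ in range(n_boot):
        sample = []
        for z, plist in by_z.items():
            idx = rng.integers(0, len(plist), len(plist))
            sample.extend(plist[i] for i in idx)
        groups = _PatternGroups(sample, spec.m)
        res = optimize.minimize(
            groups.minus2ll_vec, theta_hat, args=(spec,), method="L-BFGS-B",
            options={"ftol": tol * 1e-2, "maxiter": 2000},
        )
        p = unpack_params(res.x, spec)
        std, rg, _, _ = standardize(p, traits)
        h2_draws.append(std["h2"].to_numpy())
        rg_draws.append(rg.to_numpy())
    h2_draws = np.asarray(h2_draws)
    rg_draws = np.asarray(rg_draws)
    return {
        "h2_lo": np.nanpercentile(h2_draws, 2.5, axis=0).tolist(),
        "h2_hi": np.nanpercentile(h2_draws, 97.5, axis=0).tolist(),
        "rg_lo": np.nanpercentile(rg_draws, 2.5, axis=0).tolist(),
        "rg_hi": np.nanpercentile(rg_draws, 97.5, axis=0).tolist(),
        "n_boot": n_boot,
    }


def compare_models(
    ds: TwinDataset,
    specs: Sequence[CholeskySpec],
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[str, BiometricFit]]:
    """Fit several specs on identical data and rank them by AIC."""
    trait_sets = {tuple(s.traits) for s in specs}
    if len(trait_sets) != 1:
        raise ComparabilityError("all specs must use the same traits (same case set)")
    fits = {}
    rows = []
    for s in specs:
        f = fit_cholesky(ds, s, **fit_kwargs)
        fits[s.label] = f
        rows.append(
            {"model": s.label, "minus2lnL": f.minus2lnL, "k": f.n_params, "AIC": f.AIC}
        )
    table = pd.DataFrame(rows).sort_values(["AIC", "k"], kind="stable").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].iloc[0]
    table["best"] = [i == 0 for i in range(len(table))]
    return table, fits


def twin_correlations(ds: TwinDataset, trait: str, min_pairs: int = 3) -> dict:
    """Double-entry intraclass correlation per zygosity group."""
    pairs = to_wide(ds, [trait])
    out = {}
    for z in ("MZ", "DZ"):
        x1, x2 = [], []
        for p in pairs:
            if p.zygosity != z:
                continue
            a, b = p.values_twin1[0], p.values_twin2[0]
            if np.isnan(a) or np.isnan(b):
                continue
            x1.append(a)
            x2.append(b)
        n = len(x1)
        if n < min_pairs:
            raise ValidationError(f"need >= {min_pairs} complete {z} pairs, got {n}")
        u = np.concatenate([x1, x2])
        v = np.concatenate([x2, x1])
        out[f"r_{z}"] = float(np.corrcoef(u, v)[0, 1])
        out[f"n_{z}"] = n
    return out


def falconer_h2(r_mz: float, r_dz: float) -> float:
    """Moment-based heritability approximation 2(r_MZ - r_DZ)."""
    return 2.0 * (r_mz - r_dz)
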