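"""Synthetic twin cohorts with known generating truth.

Trait construction per individual k in a pair:

    S_k = L_a g_k + L_c c_pair + L_e e_k

with g, c, e standard normal factor vectors; MZ co-twins share g exactly,
DZ co-twins share it with correlation 0.5 via the split
g_k = sqrt(0.5) g_common + sqrt(0.5) g_unique_k (exact by construction).
Shared environment c is common to both twins; e is unique.

Wellbeing is a mixture of direct-causal and genetically confounded paths:

    y_k = sum_j gamma_j S_jk + delta . g_k + noise

so the co-twin within-pair estimator recovers gamma while delta induces
purely familial (genetic) confounding. Wave-2 wellbeing is
stability * y + fresh noise; wave-2 availability follows a logistic
retention model on wave-1 wellbeing (outcome-dependent attrition).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .twin_data import TwinDataset

WELLBEING_W1 = "wellbeing_w1"
WELLBEING_W2 = "wellbeing_w2"


@dataclass
class ItemModel:
    """Generate Likert items from a true score: load, add noise, round, clip."""

    n_items: int = 5
    loading: float = 0.85
    response_min: int = 1
    response_max: int = 7


@dataclass
class SimulationConfig:
    n_mz_pairs: int
    n_dz_pairs: int
    traits: tuple[str, ...]
    # either explicit paths ...
    L_a: np.ndarray | None = None
    L_c: np.ndarray | None = None
    L_e: np.ndarray | None = None
    # ... or shorthand (converted on construction)
    h2: Sequence[float] | None = None
    rg: np.ndarray | None = None
    # wellbeing model
    gamma: Sequence[float] = ()           # direct causal effect of each trait
    delta: Sequence[float] = ()           # confound loading on each genetic factor
    wellbeing_noise_sd: float = 1.0
    stability: float = 0.6                # wave-1 -> wave-2 carry-over
    wellbeing_w2_noise_sd: float = 0.8
    # item generation: trait name -> ItemModel
    items: dict[str, ItemModel] = field(default_factory=dict)
    # attrition (wave-2 retention): P(retain) = logistic(intercept + slope*y1)
    attrition_intercept: float = 10.0     # default: essentially no attrition
    attrition_slope: float = 0.0
    missing_pair_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ConfigError("pair counts must be >= 0")
        self.traits = tuple(self.traits)
        m = len(self.traits)
        if self.L_a is None:
            if self.h2 is None:
                raise ConfigError("provide either L_a/L_c/L_e or the h2/rg shorthand")
            self._from_shorthand(m)
        for name in ("L_a", "L_c", "L_e"):
            L = getattr(self, name)
            if L is None:
                L = np.zeros((m, m))
            L = np.asarray(L, dtype=float)
            if L.shape != (m, m):
                raise ConfigError(f"{name} must be {m}x{m}")
            setattr(self, name, L)
        if not np.isfinite(self.attrition_slope):
            raise ConfigError("attrition slope must be finite")
        if not (0.0 <= self.missing_pair_fraction < 1.0):
            raise ConfigError("missing_pair_fraction must be in [0, 1)")
        self.gamma = np.asarray(self.gamma if len(self.gamma) else np.zeros(m), dtype=float)
        self.delta = np.asarray(self.delta if len(self.delta) else np.zeros(m), dtype=float)
        if self.gamma.shape != (m,) or self.delta.shape != (m,):
            raise ConfigError("gamma and delta must have one entry per trait")

    def _from_shorthand(self, m: int):
        h2 = np.asarray(self.h2, dtype=float)
        if h2.shape != (m,) or (h2 < 0).any() or (h2 > 1).any():
            raise ConfigError("h2 must be per-trait values in [0, 1]")
        rg = np.eye(m) if self.rg is None else np.asarray(self.rg, dtype=float)
        if rg.shape != (m, m) or not np.allclose(rg, rg.T) or not np.allclose(np.diag(rg), 1.0):
            raise ConfigError("rg must be symmetric with unit diagonal")
        eig = np.linalg.eigvalsh(rg)
        if eig.min() < -1e-10:
            raise ConfigError("rg matrix is not positive semidefinite")
        d = np.sqrt(h2)
        A = np.outer(d, d) * rg
        # PSD by construction; jitter guards exact rank deficiency
        self.L_a = np.linalg.cholesky(A + 1e-12 * np.eye(m)) if h2.any() else np.zeros((m, m))
        self.L_c = np.zeros((m, m))
        self.L_e = np.diag(np.sqrt(1.0 - h2))

    def truth_record(self) -> dict:
        """JSON-serializable record of every generating parameter."""

        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, ItemModel):
                return dataclasses.asdict(v)
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(cfg: SimulationConfig, seed: int | None = None) -> tuple[TwinDataset, dict]:
    """Generate a cohort; returns (dataset, truth record). Deterministic per seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    m = len(cfg.traits)
    n_pairs = cfg.n_mz_pairs + cfg.n_dz_pairs
    if n_pairs == 0:
        raise ConfigError("no pairs to simulate")
    zyg = np.array(["MZ"] * cfg.n_mz_pairs + ["DZ"] * cfg.n_dz_pairs)

    g_common = rng.standard_normal((n_pairs, m))
    g_unique = rng.standard_normal((2, n_pairs, m))
    c_pair = rng.standard_normal((n_pairs, m))
    e = rng.standard_normal((2, n_pairs, m))

    is_dz = (zyg == "DZ")[:, None]
    g = np.empty((2, n_pairs, m))
    for k in range(2):
        g[k] = np.where(is_dz, np.sqrt(0.5) * g_common + np.sqrt(0.5) * g_unique[k], g_common)

    S = np.empty((2, n_pairs, m))
    for k in range(2):
        S[k] = g[k] @ cfg.L_a.T + c_pair @ cfg.L_c.T + e[k] @ cfg.L_e.T

    y1 = np.empty((2, n_pairs))
    y2 = np.empty((2, n_pairs))
    for k in range(2):
        y1[k] = S[k] @ cfg.gamma + g[k] @ cfg.delta + rng.normal(
            0, cfg.wellbeing_noise_sd, n_pairs
        )
    for k in range(2):
        y2[k] = cfg.stability * y1[k] + rng.normal(0, cfg.wellbeing_w2_noise_sd, n_pairs)

    # outcome-dependent wave-2 attrition
    retained = np.empty((2, n_pairs), dtype=bool)
    for k in range(2):
        p = _logistic(cfg.attrition_intercept + cfg.attrition_slope * y1[k])
        retained[k] = rng.random(n_pairs) < p
    y2 = np.where(retained, y2, np.nan)

    # sex and age are pair-level (same-sex pairs only)
    sex = rng.choice(["F", "M"], size=n_pairs)
    age = np.round(rng.normal(63.0, 4.5, n_pairs), 1)

    drop_twin2 = rng.random(n_pairs) < cfg.missing_pair_fraction

    rows = []
    for k in range(2):
        d = pd.DataFrame(
            {
                "pair_id": np.arange(1, n_pairs + 1),
                "twin_index": k + 1,
                "zygosity": zyg,
                "sex": sex,
                "age": age,
                "wave": 1,
            }
        )
        for j, t in enumerate(cfg.traits):
            d[t] = S[k][:, j]
        d[WELLBEING_W1] = y1[k]
        d[WELLBEING_W2] = y2[k]
        if k == 1:
            d = d[~drop_twin2]
        rows.append(d)
    df = pd.concat(rows, ignore_index=True).sort_values(
        ["pair_id", "twin_index"], kind="stable"
    ).reset_index(drop=True)

    # optional Likert item generation from true scores
    for trait, im in (cfg.items or {}).items():
        true = df[trait].to_numpy()
        z = (true - np.nanmean(true)) / max(np.nanstd(true), 1e-12)
        center = (im.response_min + im.response_max) / 2.0
        scale = (im.response_max - im.response_min) / 4.0
        for i in range(im.n_items):
            noise = rng.standard_normal(len(df)) * np.sqrt(max(1 - im.loading**2, 0.0))
            latent = im.loading * z + noise
            resp = np.round(center + scale * latent)
            df[f"{trait}_item{i + 1}"] = np.clip(resp, im.response_min, im.response_max)

    ds = TwinDataset(df)
    truth = cfg.truth_record()
    truth["seed_used"] = int(cfg.seed if seed is None else seed)
    return ds, truth


_SCENARIOS = {
    "causal": dict(gamma=0.3, delta=0.0),
    "confounded": dict(gamma=0.0, delta=0.4),
    "mixed": dict(gamma=0.3, delta=0.3),
    "null": dict(gamma=0.0, delta=0.0),
}


def scenario(
    name: str,
    *,
    n_mz_pairs: int = 1000,
    n_dz_pairs: int = 1000,
    h2: float = 0.4,
    seed: int = 0,
) -> SimulationConfig:
    """Canned single-trait configs exercising the co-twin inferential logic.

    causal: direct effect only; confounded: association purely via shared
    genetic factors; mixed: both (attenuation without elimination); null:
    no association.
    """
    if name not in _SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; options: {sorted(_SCENARIOS)}")
    s = _SCENARIOS[name]
    return SimulationConfig(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        traits=("social",),
        h2=[h2],
        gamma=[s["gamma"]],
        delta=[s["delta"]],
        wellbeing_noise_sd=1.0,
        seed=seed,
    )


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def truth_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
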