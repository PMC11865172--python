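"""Data model and I/O for twin cohorts.

The canonical on-disk representation is a long CSV: one row per individual,
with columns ``pair_id, twin_index, zygosity, sex, age, wave`` followed by
trait/item columns. Missing values are empty cells. The wide (one row per
pair) representation exists only in memory, as the unit over which the
biometric pair likelihood is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

CORE_COLUMNS = ("pair_id", "twin_index", "zygosity", "sex", "age", "wave")
ZYGOSITIES = ("MZ", "DZ")
SEXES = ("F", "M")


@dataclass
class TwinDataset:
    """A validated long-format twin cohort.

    Attributes
    ----------
    df:
        One row per individual. Core columns first, then trait columns.
    trait_names:
        Names of the trait/item columns, in column order.
    """

    df: pd.DataFrame
    trait_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.trait_names:
            self.trait_names = tuple(
                c for c in self.df.columns if c not in CORE_COLUMNS
            )
        report = validate_cohort(self.df)
        if report:
            raise IntegrityError(
                f"{len(report)} integrity violation(s); first: {report[0]}",
                report=report,
            )
        self.df = self.df.reset_index(drop=True)

    # -- basic views ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.df)

    @property
    def n_pairs(self) -> int:
        return self.df["pair_id"].nunique()

    def pairs(self) -> Iterable[tuple[object, pd.DataFrame]]:
        return self.df.groupby("pair_id", sort=True)

    def describe(self) -> pd.DataFrame:
        """Pair and individual counts by zygosity and sex (sums to totals)."""
        rows = []
        for (zyg, sex), grp in self.df.groupby(["zygosity", "sex"]):
            rows.append(
                {
                    "zygosity": zyg,
                    "sex": sex,
                    "n_pairs": grp["pair_id"].nunique(),
                    "n_individuals": len(grp),
                }
            )
        out = pd.DataFrame(rows, columns=["zygosity", "sex", "n_pairs", "n_individuals"])
        total = pd.DataFrame(
            [
                {
                    "zygosity": "all",
                    "sex": "all",
                    "n_pairs": self.n_pairs,
                    "n_individuals": self.n_individuals,
                }
            ]
        )
        return pd.concat([out, total], ignore_index=True)

    def subset_traits(self, traits: Sequence[str]) -> "TwinDataset":
        missing = [t for t in traits if t not in self.trait_names]
        if missing:
            raise KeyError(f"unknown trait(s): {missing}")
        cols = list(CORE_COLUMNS) + list(traits)
        return TwinDataset(self.df[cols].copy(), tuple(traits))

    def with_columns(self, new: Mapping[str, Sequence]) -> "TwinDataset":
        df = self.df.copy()
        for name, vals in new.items():
            df[name] = np.asarray(vals)
        return TwinDataset(df)


@dataclass
class WidePair:
    """One twin pair with aligned trait vectors (NaN = missing)."""

    pair_id: object
    zygosity: str
    sex: str
    age: float
    traits: tuple[str, ...]
    values_twin1: np.ndarray
    values_twin2: np.ndarray

    def __post_init__(self):
        self.values_twin1 = np.asarray(self.values_twin1, dtype=float)
        self.values_twin2 = np.asarray(self.values_twin2, dtype=float)
        if self.values_twin1.shape != (len(self.traits),) or self.values_twin2.shape != (
            len(self.traits),
        ):
            raise ValidationError("trait vectors must align with trait names")


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Return a per-row/per-pair report of invariant violations (empty = valid)."""
    problems: list[str] = []
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    bad_zyg = df.loc[~df["zygosity"].isin(ZYGOSITIES)]
    for idx, z in bad_zyg["zygosity"].items():
        problems.append(f"row {idx}: zygosity {z!r} not in {ZYGOSITIES}")
    bad_sex = df.loc[~df["sex"].isin(SEXES)]
    for idx, s in bad_sex["sex"].items():
        problems.append(f"row {idx}: sex {s!r} not in {SEXES}")
    bad_ti = df.loc[~df["twin_index"].isin([1, 2])]
    for idx, t in bad_ti["twin_index"].items():
        problems.append(f"row {idx}: twin_index {t!r} not in (1, 2)")

    dup = df.duplicated(subset=["pair_id", "twin_index"], keep=False)
    for pid in sorted(df.loc[dup, "pair_id"].unique().tolist()):
        problems.append(f"pair {pid!r}: duplicate (pair_id, twin_index)")

    for pid, grp in df.groupby("pair_id"):
        if len(grp) > 2:
            problems.append(f"pair {pid!r}: has {len(grp)} members (max 2)")
        for col in ("zygosity", "sex", "age"):
            if grp[col].nunique(dropna=False) > 1:
                problems.append(f"pair {pid!r}: discordant {col}")
    return problems


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> TwinDataset:
    """Read a long-format cohort CSV.

    Parameters
    ----------
    path:
        CSV file with a header row; empty cells are missing values.
    schema:
        Optional map from canonical column names to file column names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        rename = {src: canon for canon, src in schema.items()}
        absent = [src for src in schema.values() if src not in df.columns]
        if absent:
            raise SchemaError(f"schema refers to absent column(s): {absent}")
        df = df.rename(columns=rename)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df["twin_index"] = pd.to_numeric(df["twin_index"], errors="coerce").astype("Int64")
    df["wave"] = pd.to_numeric(df["wave"], errors="coerce").astype("Int64")
    df["twin_index"] = df["twin_index"].astype(int)
    ordered = [c for c in CORE_COLUMNS] + [c for c in df.columns if c not in CORE_COLUMNS]
    return TwinDataset(df[ordered])


def write_cohort(ds: TwinDataset, path: str | Path) -> Path:
    """Write the cohort as canonical long CSV (empty cells for missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.df.to_csv(path, index=False)
    return path


def to_wide(ds: TwinDataset, traits: Sequence[str]) -> list[WidePair]:
    """Convert to one :class:`WidePair` per pair, twins ordered by twin_index.

    Singleton pairs get an all-missing twin-2 vector.
    """
    traits = list(traits)
    if not traits:
        raise ValidationError("trait list must be non-empty")
    unknown = [t for t in traits if t not in ds.trait_names]
    if unknown:
        raise KeyError(f"unknown trait(s): {unknown}")

    df = ds.df
    meta = (
        df.groupby("pair_id", sort=True)
        .agg(zygosity=("zygosity", "first"), sex=("sex", "first"), age=("age", "first"))
    )
    pids = meta.index.to_numpy()
    mats = {}
    for ti in (1, 2):
        sub = df.loc[df["twin_index"] == ti].set_index("pair_id")
        mat = pd.DataFrame(np.nan, index=meta.index, columns=traits)
        mat.loc[sub.index, traits] = sub[traits].to_numpy(dtype=float)
        mats[ti] = mat.to_numpy(dtype=float)

    ttraits = tuple(traits)
    zyg = meta["zygosity"].to_numpy()
    sex = meta["sex"].to_numpy()
    age = meta["age"].to_numpy(dtype=float)
    return [
        WidePair(
            pair_id=pids[i],
            zygosity=zyg[i],
            sex=sex[i],
            age=age[i],
            traits=ttraits,
            values_twin1=mats[1][i],
            values_twin2=mats[2][i],
        )
        for i in range(len(pids))
    ]


def to_long(pairs: Sequence[WidePair], wave: int = 1) -> TwinDataset:
    """Inverse of :func:`to_wide`; drops all-missing twin-2 rows of singletons."""
    rows = []
    for wp in pairs:
        for ti, vec in ((1, wp.values_twin1), (2, wp.values_twin2)):
            if ti == 2 and np.all(np.isnan(vec)):
                continue
            row = {
                "pair_id": wp.pair_id,
                "twin_index": ti,
                "zygosity": wp.zygosity,
                "sex": wp.sex,
                "age": wp.age,
                "wave": wave,
            }
            row.update({t: v for t, v in zip(wp.traits, vec)})
            rows.append(row)
    if not rows:
        raise ValidationError("no pairs to convert")
    df = pd.DataFrame(rows)
    return TwinDataset(df)
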