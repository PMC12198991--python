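"""Refit group-additivity values by ordinary least squares with holdout.

The design matrix has one column per group or correction label (counts)
plus an intercept column; each thermochemical property (S°, ΔfS°, ΔfG°) is
fit independently on a shared random train/test split, and the fitted
coefficients are assembled back into a :class:`~thermogav.gav_model.GavParameterTable`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .gav_model import (
    GavParameterTable,
    GroupValues,
    GroupVector,
    PROPERTIES,
    canonical_label,
)

__all__ = [
    "DatasetRow",
    "ThermoDataset",
    "Metrics",
    "FitResult",
    "split_holdout",
    "fit_mlr",
    "metrics",
    "run_pipeline",
    "load_dataset_csv",
    "save_dataset_csv",
]

_OBS_COLUMNS = {"S": "S_J_molK", "dfS": "dfS_J_molK", "dfG": "dfG_kJ_mol"}


@dataclass(frozen=True)
class DatasetRow:
    molecule_id: str
    groups: GroupVector
    observed: Mapping[str, float]  # property -> value

    def __post_init__(self):
        bad = set(self.observed) - set(PROPERTIES)
        if bad:
            raise ValueError(f"unknown observed properties {sorted(bad)}")


@dataclass
class ThermoDataset:
    """Rows of (molecule id, group vector, observed properties).

    ``group_universe`` fixes the design-matrix column order; it must cover
    every label used by any row.
    """

    rows: list[DatasetRow]
    group_universe: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.group_universe = [canonical_label(g) for g in self.group_universe]
        ids = [r.molecule_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate molecule ids: {dupes}")
        universe = set(self.group_universe)
        used = set()
        for r in self.rows:
            used.update(r.groups.all_counts())
        missing = sorted(used - universe)
        if not self.group_universe:
            self.group_universe = sorted(used)
        elif missing:
            raise ValueError(f"group_universe missing labels: {missing}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.molecule_id for r in self.rows]

    def subset(self, ids: Sequence[str]) -> "ThermoDataset":
        wanted = set(ids)
        return ThermoDataset(
            rows=[r for r in self.rows if r.molecule_id in wanted],
            group_universe=list(self.group_universe),
        )

    def design_matrix(self, with_intercept: bool = True) -> np.ndarray:
        """n x p count matrix in ``group_universe`` order (+ intercept col)."""
        X = np.zeros((len(self.rows), len(self.group_universe)))
        col = {g: k for k, g in enumerate(self.group_universe)}
        for i, r in enumerate(self.rows):
            for label, n in r.groups.all_counts().items():
                X[i, col[label]] = n
        if with_intercept:
            X = np.hstack([X, np.ones((len(self.rows), 1))])
        return X

    def observed_vector(self, property: str) -> np.ndarray:
        vals = []
        for r in self.rows:
            if property not in r.observed:
                raise ValueError(
                    f"molecule {r.molecule_id!r} has no observed {property!r}"
                )
            vals.append(r.observed[property])
        return np.asarray(vals, dtype=float)


class Metrics(NamedTuple):
    r2: float
    mae: float
    rmse: float


@dataclass
class FitResult:
    """OLS fit of one property: coefficients, intercept, per-split metrics."""

    property: str
    coefficients: dict[str, float]
    intercept: float
    train_metrics: Metrics
    test_metrics: Optional[Metrics]
    train_ids: list[str]
    test_ids: list[str]
    seed: Optional[int]
    rank: int
    aliased: list[str] = field(default_factory=list)

    def predict(self, ds: ThermoDataset) -> np.ndarray:
        X = ds.design_matrix(with_intercept=False)
        beta = np.array([self.coefficients[g] for g in ds.group_universe])
        return X @ beta + self.intercept

    def to_dict(self) -> dict:
        return {
            "property": self.property,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "metrics": {
                "train": self.train_metrics._asdict(),
                "test": self.test_metrics._asdict() if self.test_metrics else None,
            },
            "split": {"train": self.train_ids, "test": self.test_ids},
            "seed": self.seed,
            "rank": self.rank,
            "aliased_columns": self.aliased,
        }


def split_holdout(
    ds: ThermoDataset, train_frac: float = 0.7, seed: int = 42
) -> tuple[ThermoDataset, ThermoDataset]:
    """Single random train/test partition without replacement.

    Train size is floor(train_frac * n); the split is uniform over subsets
    and fully determined by ``seed``. Both parts must be nonempty.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    n = len(ds)
    n_train = math.floor(train_frac * n)
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"dataset of size {n} cannot be split {train_frac:.0%}/rest")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = set(perm[:n_train].tolist())
    ids = ds.ids
    train_ids = [ids[i] for i in range(n) if i in train_idx]
    test_ids = [ids[i] for i in range(n) if i not in train_idx]
    return ds.subset(train_ids), ds.subset(test_ids)


def metrics(predicted: Sequence[float], observed: Sequence[float]) -> Metrics:
    """R², MAE and RMSE of predictions against observations.

    R² = 1 - SS_res/SS_tot; a zero-variance observation vector makes R²
    undefined and is an error rather than a NaN.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("predicted and observed must be equal-length nonempty vectors")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance; R² is undefined")
    err = p - o
    ss_res = float(np.sum(err**2))
    return Metrics(
        r2=1.0 - ss_res / ss_tot,
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
    )


def _find_aliased(X: np.ndarray, rank: int, labels: Sequence[str]) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    aliased = []
    basis = np.empty((X.shape[0], 0))
    r = 0
    for k in range(X.shape[1]):
        trial = np.hstack([basis, X[:, [k]]])
        tr = np.linalg.matrix_rank(trial)
        if tr > r:
            basis, r = trial, tr
        else:
            aliased.append(labels[k] if k < len(labels) else "<intercept>")
    return aliased


def fit_mlr(
    train: ThermoDataset,
    property: str,
    seed: Optional[int] = None,
    test: Optional[ThermoDataset] = None,
) -> FitResult:
    """Ordinary least squares of one property on group counts + intercept.

    Rank-deficient designs are solved by the minimum-norm solution and a
    warning names the aliased columns; predictions are unaffected by the
    aliasing.
    """
    if property not in PROPERTIES:
        raise ValueError(f"property must be one of {PROPERTIES}")
    if len(train) == 0:
        raise ValueError("empty training set")
    X = train.design_matrix(with_intercept=True)
    if not np.any(X[:, :-1]):
        # all-zero group counts: the model degenerates to the intercept
        pass
    y = train.observed_vector(property)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    aliased: list[str] = []
    if rank < X.shape[1]:
        aliased = _find_aliased(X, rank, list(train.group_universe))
        warnings.warn(
            f"rank-deficient design for {property} (rank {rank} < {X.shape[1]}); "
            f"minimum-norm solution used; aliased columns: {aliased}",
            stacklevel=2,
        )
    coefficients = dict(zip(train.group_universe, beta[:-1].tolist()))
    intercept = float(beta[-1])
    result = FitResult(
        property=property,
        coefficients=coefficients,
        intercept=intercept,
        train_metrics=metrics(X @ beta, y),
        test_metrics=None,
        train_ids=train.ids,
        test_ids=test.ids if test is not None else [],
        seed=seed,
        rank=int(rank),
        aliased=aliased,
    )
    if test is not None and len(test):
        result.test_metrics = metrics(result.predict(test), test.observed_vector(property))
    return result


def run_pipeline(
    ds: ThermoDataset,
    properties: Sequence[str] = PROPERTIES,
    train_frac: float = 0.7,
    seed: int = 42,
) -> tuple[GavParameterTable, dict[str, FitResult]]:
    """One shared holdout split, one OLS fit per property, assembled table.

    Properties not fit are stored as NaN in the returned table.
    """
    train, test = split_holdout(ds, train_frac=train_frac, seed=seed)
    fits: dict[str, FitResult] = {}
    for prop in properties:
        fits[prop] = fit_mlr(train, prop, seed=seed, test=test)

    def triple(getter) -> GroupValues:
        return GroupValues(
            *(getter(fits[p]) if p in fits else float("nan") for p in PROPERTIES)
        )

    table = GavParameterTable(
        values={
            g: triple(lambda f, g=g: f.coefficients[g]) for g in ds.group_universe
        },
        intercept=triple(lambda f: f.intercept),
        provenance=(
            f"OLS refit on {len(ds)} molecules, holdout {train_frac:.0%} train, seed {seed}"
        ),
    )
    return table, fits


# ---------------------------------------------------------------------------
# dataset IO


def save_dataset_csv(ds: ThermoDataset, path) -> None:
    records = []
    for r in ds.rows:
        rec: dict = {"molecule_id": r.molecule_id}
        for prop, col in _OBS_COLUMNS.items():
            if prop in r.observed:
                rec[col] = r.observed[prop]
        for label, n in r.groups.all_counts().items():
            rec[f"group:{label}"] = n
        records.append(rec)
    cols = ["molecule_id"] + [
        c for c in _OBS_COLUMNS.values() if any(c in r for r in records)
    ] + [f"group:{g}" for g in ds.group_universe]
    pd.DataFrame(records).reindex(columns=cols).fillna(0.0).to_csv(path, index=False)


def load_dataset_csv(path) -> ThermoDataset:
    """Read a dataset CSV: molecule_id, observed columns, ``group:<label>``."""
    df = pd.read_csv(path)
    if "molecule_id" not in df.columns:
        raise ValueError("dataset CSV needs a molecule_id column")
    group_cols = [c for c in df.columns if c.startswith("group:")]
    rows = []
    for _, rec in df.iterrows():
        observed = {}
        for prop, col in _OBS_COLUMNS.items():
            if col in df.columns and pd.notna(rec[col]):
                observed[prop] = float(rec[col])
        counts = {
            c[len("group:"):]: float(rec[c])
            for c in group_cols
            if pd.notna(rec[c]) and rec[c] != 0
        }
        rows.append(DatasetRow(str(rec["molecule_id"]), GroupVector(counts), observed))
    universe = [canonical_label(c[len("group:"):]) for c in group_cols]
    return ThermoDataset(rows=rows, group_universe=universe)


def save_fit_report(fits: Mapping[str, FitResult], path) -> None:
    with open(Path(path), "w") as fh:
        json.dump({p: f.to_dict() for p, f in fits.items()}, fh, indent=2)
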