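"""Feed-forward surrogate for particle-wall mean collision numbers.

A full Lagrangian run takes seconds to minutes per condition; scanning the
six-dimensional condition space (particle size and density, pipe diameter
and length, air velocity, injection vertical speed) this way is slow.  This
module builds a simulator-backed database over those six inputs, min-max
normalizes it, splits it 70/15/15 into train/validation/test, and trains an
ensemble of small 6-H-1 networks (tanh hidden layer, linear output, default
H = 6, 30 members with independent initializations) whose averaged output
predicts the mean collision number in a few microseconds.

RMSE values are always reported in denormalized collision-number units.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from ._errors import (
    DegenerateNormalizationError,
    ExtrapolationWarning,
    InvalidParameterError,
)
from .flow_field import AIR, GasProperties
from .io_fixtures import derive_seed
from .particle_tracking import Condition, TrackingConfig, run_condition

__all__ = [
    "FEATURES",
    "FEATURE_RANGES",
    "TARGET_RANGE",
    "MinMaxNormalizer",
    "SurrogateDataset",
    "SurrogateEnsemble",
    "assign_splits",
    "latin_hypercube_plan",
    "build_database",
    "train_ensemble",
    "neuron_sweep",
]

#: The six surrogate inputs, in database column order.
FEATURES = (
    "particle_size_um",
    "particle_density_kg_m3",
    "pipe_diameter_m",
    "pipe_length_m",
    "air_velocity_m_s",
    "vertical_velocity_m_s",
)

#: Input ranges the database is sampled over.
FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "particle_size_um": (10.0, 600.0),
    "particle_density_kg_m3": (1410.0, 7850.0),
    "pipe_diameter_m": (0.002, 0.006),
    "pipe_length_m": (0.25, 1.5),
    "air_velocity_m_s": (6.5, 36.0),
    "vertical_velocity_m_s": (0.0, 1.2),
}

#: Sanity range of the output (mean collision number) over those conditions.
TARGET_RANGE = (0.6, 80.0)

SCHEMA_VERSION = 1


def assign_splits(n: int, seed: int | None = None) -> np.ndarray:
    """Random 70/15/15 train/validation/test assignment for ``n`` points.

    Counts follow a floor rule: train = floor(0.70 n), validation =
    nearest-int(0.15 n), test = remainder — for n = 197 this yields
    137/30/30.
    """
    if n < 3:
        raise InvalidParameterError("need at least 3 points to split")
    n_train = int(np.floor(0.70 * n))
    n_val = round(0.15 * n)
    labels = np.array(
        ["train"] * n_train + ["validation"] * n_val + ["test"] * (n - n_train - n_val)
    )
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(n)]


@dataclass
class MinMaxNormalizer:
    """Per-feature (and target) min-max state fitted on the training split."""

    feature_min: np.ndarray
    feature_max: np.ndarray
    target_min: float
    target_max: float

    @classmethod
    def fit(cls, x: np.ndarray, y: np.ndarray) -> "MinMaxNormalizer":
        fmin = x.min(axis=0)
        fmax = x.max(axis=0)
        constant = np.flatnonzero(fmax - fmin <= 0)
        if constant.size:
            names = ", ".join(FEATURES[i] for i in constant)
            raise DegenerateNormalizationError(
                f"constant feature(s) on the training set: {names}"
            )
        tmin, tmax = float(y.min()), float(y.max())
        if tmax - tmin <= 0:
            # a constant target is still trainable; avoid division by zero
            tmax = tmin + 1.0
        return cls(fmin, fmax, tmin, tmax)

    def transform(self, x: np.ndarray, warn: bool = True) -> np.ndarray:
        xn = (np.asarray(x, dtype=float) - self.feature_min) / (
            self.feature_max - self.feature_min
        )
        if warn and (np.any(xn < -1e-9) or np.any(xn > 1 + 1e-9)):
            warnings.warn(
                "input outside the training range: surrogate is extrapolating",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return xn

    def inverse_transform(self, xn: np.ndarray) -> np.ndarray:
        return np.asarray(xn, dtype=float) * (
            self.feature_max - self.feature_min
        ) + self.feature_min

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.target_min) / (
            self.target_max - self.target_min
        )

    def inverse_transform_target(self, yn: np.ndarray) -> np.ndarray:
        return np.asarray(yn, dtype=float) * (
            self.target_max - self.target_min
        ) + self.target_min


@dataclass
class SurrogateDataset:
    """Simulator-backed database with split assignment and normalizer state."""

    features: pd.DataFrame  # columns = FEATURES
    targets: np.ndarray  # mean collision numbers
    split: np.ndarray  # "train" | "validation" | "test" per row
    target_sem: np.ndarray  # Monte-Carlo SEM of each target
    normalizer: MinMaxNormalizer | None  # None for degenerate (<3 point) sets
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.targets)

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.split == which
        return self.features.to_numpy(float)[mask], self.targets[mask]

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out["mean_collision_number"] = self.targets
        out["target_sem"] = self.target_sem
        out["split"] = self.split
        return out


def latin_hypercube_plan(n_points: int, seed: int | None = None) -> pd.DataFrame:
    """Latin-hypercube sample of ``n_points`` conditions over the input ranges."""
    if n_points < 1:
        raise InvalidParameterError("n_points must be >= 1")
    sampler = qmc.LatinHypercube(d=len(FEATURES), seed=seed)
    unit = sampler.random(n_points)
    lo = np.array([FEATURE_RANGES[f][0] for f in FEATURES])
    hi = np.array([FEATURE_RANGES[f][1] for f in FEATURES])
    return pd.DataFrame(qmc.scale(unit, lo, hi), columns=list(FEATURES))


def _condition_from_row(row: pd.Series) -> Condition:
    return Condition(
        particle_diameter=float(row["particle_size_um"]) * 1e-6,
        particle_density=float(row["particle_density_kg_m3"]),
        pipe_length=float(row["pipe_length_m"]),
        pipe_diameter=float(row["pipe_diameter_m"]),
        air_velocity=float(row["air_velocity_m_s"]),
        vertical_speed=float(row["vertical_velocity_m_s"]),
    )


def build_database(
    plan: pd.DataFrame | None = None,
    n_points: int = 197,
    gas: GasProperties = AIR,
    n_particles: int = 100,
    seed: int = 0,
) -> SurrogateDataset:
    """Run the simulator at every plan point and assemble the database.

    The default plan is a 197-point Latin hypercube over the six input
    ranges (197 = 137 + 30 + 30 under the 70/15/15 split).  Failing points
    are dropped and reported in the provenance.
    """
    if plan is None:
        plan = latin_hypercube_plan(n_points, seed=derive_seed(seed, "plan"))
    missing = set(FEATURES) - set(plan.columns)
    if missing:
        raise InvalidParameterError(f"plan lacks feature column(s): {sorted(missing)}")

    targets, sems, ok_rows, failures = [], [], [], []
    for i, (_, row) in enumerate(plan.iterrows()):
        cond = _condition_from_row(row)
        cfg = TrackingConfig(
            n_particles=n_particles, rng_seed=derive_seed(seed, "db-point", i)
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summary = run_condition(cond, gas=gas, config=cfg)
        except Exception as exc:  # noqa: BLE001 - per-point isolation
            failures.append({"index": i, "error": f"{type(exc).__name__}: {exc}"})
            continue
        targets.append(summary.mean_collision_number)
        sems.append(summary.collision_count_sem)
        ok_rows.append(i)

    features = plan.iloc[ok_rows].reset_index(drop=True)[list(FEATURES)]
    targets_arr = np.asarray(targets)
    if len(features) < 3:
        # degenerate database (e.g. a single probe point): everything is
        # "train" and no normalizer can be fitted
        split = np.array(["train"] * len(features))
        normalizer = None
    else:
        split = assign_splits(len(features), seed=derive_seed(seed, "split"))
        train_mask = split == "train"
        normalizer = MinMaxNormalizer.fit(
            features.to_numpy(float)[train_mask], targets_arr[train_mask]
        )
    return SurrogateDataset(
        features=features,
        targets=targets_arr,
        split=split,
        target_sem=np.asarray(sems),
        normalizer=normalizer,
        provenance={
            "seed": seed,
            "n_particles": n_particles,
            "n_requested": len(plan),
            "n_failed": len(failures),
            "failures": failures,
        },
    )


class _WeightsNet:
    """Minimal 6-H-1 tanh/linear network evaluated from stored weights."""

    def __init__(self, coefs: list[np.ndarray], intercepts: list[np.ndarray]):
        self.coefs = [np.asarray(c, dtype=float) for c in coefs]
        self.intercepts = [np.asarray(b, dtype=float) for b in intercepts]

    def predict(self, xn: np.ndarray) -> np.ndarray:
        h = np.tanh(np.asarray(xn, float) @ self.coefs[0] + self.intercepts[0])
        return (h @ self.coefs[1] + self.intercepts[1]).ravel()


def _train_member(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    hidden_neurons: int,
    seed: int,
    chunk_iter: int = 150,
    max_chunks: int = 30,
    patience: int = 8,
) -> _WeightsNet:
    """Quasi-Newton training with validation-based early stopping.

    Optimizes in chunks of L-BFGS iterations, snapshotting the weights at
    the best validation RMSE seen so far; stops once the validation error
    fails to improve for ``patience`` consecutive chunks.
    """
    model = MLPRegressor(
        hidden_layer_sizes=(hidden_neurons,),
        activation="tanh",
        solver="lbfgs",
        max_iter=chunk_iter,
        warm_start=True,
        random_state=seed,
        tol=1e-8,
        alpha=1e-5,
    )
    best_rmse = np.inf
    best_weights: tuple | None = None
    stale = 0
    for _ in range(max_chunks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(x_train, y_train)
        val_rmse = float(np.sqrt(np.mean((model.predict(x_val) - y_val) ** 2)))
        if val_rmse < best_rmse - 1e-9:
            best_rmse = val_rmse
            best_weights = (
                copy.deepcopy(model.coefs_),
                copy.deepcopy(model.intercepts_),
            )
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if best_weights is None or not all(
        np.all(np.isfinite(w)) for w in best_weights[0] + best_weights[1]
    ):
        raise RuntimeError("member failed to produce finite weights")
    return _WeightsNet(*best_weights)


@dataclass
class SurrogateEnsemble:
    """Average of independently initialized 6-H-1 networks."""

    members: list[_WeightsNet]
    normalizer: MinMaxNormalizer
    hidden_neurons: int
    member_rmse: np.ndarray  # per-member test RMSE, collision-number units
    mean_rmse: float
    n_failed_members: int = 0

    def predict(self, features) -> np.ndarray:
        """Predict mean collision numbers for rows of physical-unit features.

        Accepts a DataFrame with the six feature columns or an (n, 6) array
        in :data:`FEATURES` order; returns denormalized collision numbers.
        """
        if isinstance(features, pd.DataFrame):
            x = features[list(FEATURES)].to_numpy(float)
        else:
            x = np.atleast_2d(np.asarray(features, dtype=float))
        xn = self.normalizer.transform(x)
        preds = np.stack([m.predict(xn) for m in self.members])
        return self.normalizer.inverse_transform_target(preds.mean(axis=0))

    def predict_members(self, features) -> np.ndarray:
        """Per-member predictions, shape (n_members, n_points)."""
        if isinstance(features, pd.DataFrame):
            x = features[list(FEATURES)].to_numpy(float)
        else:
            x = np.atleast_2d(np.asarray(features, dtype=float))
        xn = self.normalizer.transform(x)
        return self.normalizer.inverse_transform_target(
            np.stack([m.predict(xn) for m in self.members])
        )

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "hidden_neurons": self.hidden_neurons,
            "member_rmse": self.member_rmse.tolist(),
            "mean_rmse": self.mean_rmse,
            "normalizer": {
                "feature_min": self.normalizer.feature_min.tolist(),
                "feature_max": self.normalizer.feature_max.tolist(),
                "target_min": self.normalizer.target_min,
                "target_max": self.normalizer.target_max,
            },
            "members": [
                {
                    "coefs": [c.tolist() for c in m.coefs],
                    "intercepts": [b.tolist() for b in m.intercepts],
                }
                for m in self.members
            ],
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateEnsemble":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise InvalidParameterError(
                f"unsupported model schema {doc.get('schema_version')!r}"
            )
        norm = MinMaxNormalizer(
            feature_min=np.asarray(doc["normalizer"]["feature_min"]),
            feature_max=np.asarray(doc["normalizer"]["feature_max"]),
            target_min=doc["normalizer"]["target_min"],
            target_max=doc["normalizer"]["target_max"],
        )
        members = [
            _WeightsNet(m["coefs"], m["intercepts"]) for m in doc["members"]
        ]
        return cls(
            members=members,
            normalizer=norm,
            hidden_neurons=doc["hidden_neurons"],
            member_rmse=np.asarray(doc["member_rmse"]),
            mean_rmse=doc["mean_rmse"],
        )


def train_ensemble(
    dataset: SurrogateDataset,
    hidden_neurons: int = 6,
    n_members: int = 30,
    seed: int = 0,
) -> SurrogateEnsemble:
    """Train the default 30-member ensemble on a split, normalized database.

    Each member is a 6-H-1 tanh network with its own seeded initialization,
    trained on the train split with validation-based early stopping; the
    ensemble prediction is the arithmetic mean of member outputs.  Members
    that fail to converge are dropped; training aborts if more than 20% fail.
    """
    if hidden_neurons < 1 or n_members < 1:
        raise InvalidParameterError("hidden_neurons and n_members must be >= 1")
    if dataset.normalizer is None:
        raise InvalidParameterError("dataset is too small to train on (no normalizer)")
    norm = dataset.normalizer
    x_tr, y_tr = dataset.subset("train")
    x_va, y_va = dataset.subset("validation")
    x_te, y_te = dataset.subset("test")
    xn_tr, yn_tr = norm.transform(x_tr), norm.transform_target(y_tr)
    xn_va, yn_va = norm.transform(x_va, warn=False), norm.transform_target(y_va)

    members: list[_WeightsNet] = []
    rmses: list[float] = []
    failed = 0
    for i in range(n_members):
        try:
            net = _train_member(
                xn_tr, yn_tr, xn_va, yn_va, hidden_neurons,
                seed=derive_seed(seed, "member", hidden_neurons, i),
            )
        except RuntimeError:
            failed += 1
            continue
        members.append(net)
        pred = norm.inverse_transform_target(net.predict(norm.transform(x_te, warn=False)))
        rmses.append(float(np.sqrt(np.mean((pred - y_te) ** 2))))
    if len(members) < max(1, int(np.ceil(0.8 * n_members))):
        raise RuntimeError(
            f"only {len(members)}/{n_members} members converged (< 80%)"
        )
    return SurrogateEnsemble(
        members=members,
        normalizer=norm,
        hidden_neurons=hidden_neurons,
        member_rmse=np.asarray(rmses),
        mean_rmse=float(np.mean(rmses)),
        n_failed_members=failed,
    )


def neuron_sweep(
    dataset: SurrogateDataset,
    candidates=range(1, 11),
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Hidden-layer-size study: mean test RMSE of ``repeats`` seeded networks per H.

    Returns a table sorted by H with columns ``hidden_neurons`` and
    ``mean_rmse``; the optimum is the argmin row (``is_best`` column).
    """
    norm = dataset.normalizer
    x_tr, y_tr = dataset.subset("train")
    x_va, y_va = dataset.subset("validation")
    x_te, y_te = dataset.subset("test")
    xn_tr, yn_tr = norm.transform(x_tr), norm.transform_target(y_tr)
    xn_va, yn_va = norm.transform(x_va, warn=False), norm.transform_target(y_va)
    xn_te = norm.transform(x_te, warn=False)

    rows = []
    for h in candidates:
        cell = []
        for rep in range(repeats):
            net = _train_member(
                xn_tr, yn_tr, xn_va, yn_va, int(h),
                seed=derive_seed(seed, "sweep", h, rep),
            )
            pred = norm.inverse_transform_target(net.predict(xn_te))
            cell.append(float(np.sqrt(np.mean((pred - y_te) ** 2))))
        rows.append({"hidden_neurons": int(h), "mean_rmse": float(np.mean(cell))})
    table = pd.DataFrame(rows).sort_values("hidden_neurons").reset_index(drop=True)
    table["is_best"] = table["mean_rmse"] == table["mean_rmse"].min()
    return table
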