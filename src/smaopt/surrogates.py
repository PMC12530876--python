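"""Surrogate regression families with a uniform train/predict contract.

Five families are compared for predicting bulk-phase density from the four
Lennard-Jones parameters: ordinary least squares, polynomial regression
(full multivariate basis of total degree d), random-forest regression
(t trees), Gaussian-process regression (RBF / Matern / rational-quadratic
kernels) and a feed-forward neural network.  All are fitted through
scikit-learn; the value added here is the uniform :class:`ModelSpec` /
:class:`SurrogateModel` contract the optimization loop relies on.

Inputs are standardized per dimension (training-split statistics) before
polynomial, Gaussian-process and network fitting; forests and plain linear
fits consume raw values.  Fitting is deterministic given ``train_seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    RationalQuadratic,
)
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .data import DensityDataset
from .errors import ContractError, TrainingError
from .space import LJParamSet, ParameterSpace, contains

FAMILIES = ("linear", "polynomial", "random_forest", "gaussian_process", "fnn")

#: hyperparameter grids of the comparison study
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "linear": [{}],
    "polynomial": [{"degree": d} for d in range(1, 11)],
    "random_forest": [{"n_trees": t} for t in (10, 100, 250, 500, 750, 1000)],
    "gaussian_process": [{"kernel": k} for k in ("rbf", "matern", "rq")],
    "fnn": [{}],
}


# ---------------------------------------------------------------------------
# metrics


def mape(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Mean absolute percentage error as a fraction: (1/n) sum |y-yhat|/|y|."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 1:
        raise ContractError("mape needs two equal-length 1-D vectors, n >= 1")
    if np.any(y == 0):
        raise ContractError("mape undefined for zero targets")
    return float(np.mean(np.abs(y - yhat) / np.abs(y)))


def r2(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ContractError("r2 needs two equal-length 1-D vectors, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ContractError("r2 undefined for a constant target vector")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


@dataclass(frozen=True)
class MetricReport:
    """MAPE and R^2 of one model on one evaluation set."""

    mape: float
    r2: float
    mode: str  # "IST" or "OST"
    n_eval: int


# ---------------------------------------------------------------------------
# model specification and training


@dataclass(frozen=True)
class ModelSpec:
    """Family + hyperparameters + training seed.

    Recognized hyperparameters: ``degree`` (polynomial, 1..10), ``n_trees``
    (random forest), ``kernel`` (gaussian process: "rbf", "matern", "rq"),
    and for the network ``hidden_layers``, ``learning_rate``, ``epochs``,
    ``batch_size``.  Values outside the study grids are allowed.
    """

    family: str
    hyperparams: tuple[tuple[str, object], ...] = ()
    train_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ContractError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        allowed = {
            "linear": set(),
            "polynomial": {"degree"},
            "random_forest": {"n_trees"},
            "gaussian_process": {"kernel"},
            "fnn": {"hidden_layers", "learning_rate", "epochs", "batch_size"},
        }[self.family]
        bad = [k for k, _ in self.hyperparams if k not in allowed]
        if bad:
            raise ContractError(f"hyperparameters {bad} not valid for family {self.family!r}")

    @classmethod
    def make(cls, family: str, train_seed: int = 0, **hyperparams) -> "ModelSpec":
        return cls(family, tuple(sorted(hyperparams.items())), train_seed)

    def hp(self) -> dict:
        return dict(self.hyperparams)

    def label(self) -> str:
        hp = json.dumps(self.hp(), sort_keys=True)
        return f"{self.family}{hp}"


def _build_estimator(spec: ModelSpec, n_train: int):
    hp = spec.hp()
    if spec.family == "linear":
        return LinearRegression()
    if spec.family == "polynomial":
        degree = int(hp.get("degree", 2))
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=degree, include_bias=True)),
                ("ols", LinearRegression(fit_intercept=False)),
            ]
        )
    if spec.family == "random_forest":
        return RandomForestRegressor(
            n_estimators=int(hp.get("n_trees", 100)),
            random_state=spec.train_seed,
            bootstrap=True,
        )
    if spec.family == "gaussian_process":
        name = hp.get("kernel", "rq")
        d = 4
        if name == "rbf":
            core = RBF(length_scale=np.ones(d), length_scale_bounds=(1e-2, 1e3))
        elif name == "matern":
            core = Matern(length_scale=np.ones(d), nu=2.5, length_scale_bounds=(1e-2, 1e3))
        elif name == "rq":
            core = RationalQuadratic(length_scale=1.0, alpha=1.0,
                                     length_scale_bounds=(1e-2, 1e3))
        elif name == "multiscale":
            # sum of an isotropic rational-quadratic (global trend, mixed
            # length scales) and an anisotropic RBF (steep local structure);
            # the recommended surrogate for optimization at small sample sizes
            core = None
        else:
            raise ContractError(f"unknown gaussian-process kernel {name!r}")
        if name == "multiscale":
            kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RationalQuadratic(
                length_scale=1.0, alpha=1.0, length_scale_bounds=(1e-2, 1e3)
            ) + ConstantKernel(0.1, (1e-6, 1e3)) * RBF(
                length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e3)
            )
        else:
            kernel = ConstantKernel(1.0, (1e-3, 1e3)) * core
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-6,  # relative observation noise on the standardized target
            n_restarts_optimizer=5,
            normalize_y=True,
            random_state=spec.train_seed,
        )
        return Pipeline([("scale", StandardScaler()), ("gp", gp)])
    if spec.family == "fnn":
        hidden = tuple(hp.get("hidden_layers", (64, 64)))
        # early stopping needs a validation split; skip it on tiny datasets
        early = n_train >= 20
        net = MLPRegressor(
            hidden_layer_sizes=hidden,
            activation="relu",
            solver="adam",
            learning_rate_init=float(hp.get("learning_rate", 1e-3)),
            max_iter=int(hp.get("epochs", 2000)),
            batch_size=hp.get("batch_size", "auto"),
            early_stopping=early,
            validation_fraction=0.1,
            n_iter_no_change=25,
            random_state=spec.train_seed,
        )
        reg = TransformedTargetRegressor(regressor=net, transformer=StandardScaler())
        return Pipeline([("scale", StandardScaler()), ("net", reg)])
    raise ContractError(f"unknown family {spec.family!r}")


@dataclass
class SurrogateModel:
    """A fitted surrogate with a uniform predict contract."""

    spec: ModelSpec
    estimator: object
    input_space: ParameterSpace | None = None
    fingerprint: str = ""

    def predict(self, p: "LJParamSet | np.ndarray | Sequence[LJParamSet]"):
        """Predict density (kg/m^3) for one point or an ordered batch.

        Points outside the model's input space trigger a warning (the
        optimizer clamps before calling), never an error.
        """
        if isinstance(p, LJParamSet):
            arr, scalar = p.as_array()[None, :], True
        else:
            if not isinstance(p, np.ndarray) and len(p) and isinstance(p[0], LJParamSet):
                p = np.array([q.as_array() for q in p])
            arr = np.atleast_2d(np.asarray(p, dtype=float))
            scalar = np.asarray(p).ndim == 1
        if self.input_space is not None:
            inside = contains(self.input_space, arr)
            if not np.all(inside):
                warnings.warn(
                    "predicting outside the surrogate's input space",
                    RuntimeWarning,
                    stacklevel=2,
                )
        out = np.asarray(self.estimator.predict(arr), dtype=float)
        return float(out[0]) if scalar else out


def train(
    spec: ModelSpec,
    data: DensityDataset,
    input_space: ParameterSpace | None = None,
    fingerprint: str = "",
) -> SurrogateModel:
    """Fit one surrogate on a preprocessed (all-valid) dataset.

    Deterministic given ``(spec, data)``: stochastic families (forest
    bootstrap, network initialization and shuffling, kernel restarts) draw
    from ``spec.train_seed``.
    """
    if len(data) == 0:
        raise TrainingError("cannot train on an empty dataset")
    if not data.all_valid():
        raise TrainingError("dataset contains invalid records; preprocess first")
    X, y = data.params, data.densities
    if spec.family == "polynomial":
        degree = int(spec.hp().get("degree", 2))
        n_features = PolynomialFeatures(degree=degree).fit(X[:1]).n_output_features_
        if len(X) < n_features:
            raise TrainingError(
                f"polynomial degree {degree} needs >= {n_features} samples, got {len(X)}"
            )
    est = _build_estimator(spec, n_train=len(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from small fits
        est.fit(X, y)
    return SurrogateModel(spec, est, input_space, fingerprint or data.name)


def evaluate(model: SurrogateModel, data: DensityDataset, mode: str) -> MetricReport:
    """MAPE and R^2 of ``model`` on ``data``, labeled IST or OST."""
    if mode not in ("IST", "OST"):
        raise ContractError(f"mode must be 'IST' or 'OST', got {mode!r}")
    yhat = model.predict(data.params)
    return MetricReport(mape(data.densities, yhat), r2(data.densities, yhat), mode, len(data))
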