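"""Regressor-agnostic hyperparameter search with learning-curve penalties.

Model selection here does not minimise cross-validated error alone: a
model that back-computes known data accurately but generalises poorly is
penalised through learning-curve analysis (LCA).  For candidate
hyperparameters, k-fold cross-validation is run at increasing data
fractions; the search loss combines the CV mean absolute error at the
largest fraction with hinge penalties for an overfitting gap (CV err
above train err) and a rising curve (more data making CV err worse):

    loss = cv_mae(f_max)
         + lambda_gap   * max(0, cv_mae(f_max) - train_mae(f_max))
         + lambda_slope * max(0, cv_mae(f_max) - cv_mae(f_min))

During tuning the curve uses two fractions (0.5, 1.0); final
diagnostics use 20 points on [0.5, 1.0].  All metrics are computed on
log10 mole-fraction solubility.

The sampler is a contract, not a dependency: random, exhaustive-grid
and a lightweight tree-structured-Parzen-style sampler are provided and
interchangeable, and anything honouring the same interface plugs in.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, HistGradientBoostingRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, NuSVR

__all__ = [
    "MetricSet",
    "LearningCurve",
    "RegressorSpec",
    "ModelSearchResult",
    "FAMILY_REGISTRY",
    "register_family",
    "build_estimator",
    "split_train_test",
    "compute_metrics",
    "learning_curve_analysis",
    "custom_loss",
    "custom_loss_terms",
    "tune",
    "rank_models",
    "RandomSampler",
    "GridSampler",
    "TPESampler",
    "clip_log10",
]

logger = logging.getLogger(__name__)

#: Predictions are clipped to this open interval before taking log10.
X_CLIP = (1e-12, 1.0)


def clip_log10(x: np.ndarray) -> np.ndarray:
    """log10 of mole fractions with clipping to (1e-12, 1) for safety."""
    return np.log10(np.clip(np.asarray(x, dtype=float), X_CLIP[0], X_CLIP[1]))


# ---------------------------------------------------------------------------
# Metrics

@dataclass(frozen=True)
class MetricSet:
    """Error metrics on the log10 mole-fraction scale."""

    mae: float
    rmsd: float
    mape_percent: float
    r2: float | None

    def as_dict(self) -> dict:
        return {
            "mae": self.mae, "rmsd": self.rmsd,
            "mape_percent": self.mape_percent, "r2": self.r2,
        }


def compute_metrics(y_true, y_pred) -> MetricSet:
    """MAE, RMSD, MAPE (%) and R^2 between log10-solubility vectors.

    MAPE is relative to the true log-values; R^2 is reported as missing
    (``None``) when the truth has zero variance.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-d arrays")
    if np.any(yt == 0.0):
        raise ValueError("MAPE undefined: y_true contains zeros")
    e = yp - yt
    mae = float(np.mean(np.abs(e)))
    rmsd = float(np.sqrt(np.mean(e * e)))
    mape = float(100.0 * np.mean(np.abs(e / yt)))
    sst = float(np.sum((yt - yt.mean()) ** 2))
    if sst == 0.0:
        r2 = None
    else:
        r2 = float(1.0 - np.sum(e * e) / sst)
    return MetricSet(mae=mae, rmsd=rmsd, mape_percent=mape, r2=r2)


# ---------------------------------------------------------------------------
# Train/test split

def split_train_test(
    record_ids: Sequence,
    class_tags: Sequence[str],
    fraction_train: float = 2.0 / 3.0,
    seed: int = 0,
) -> tuple[list, list]:
    """Seeded, class-stratified split into training and test ids.

    Within each provenance class the ids are shuffled and the first
    ``round(fraction * n)`` (clamped to [1, n-1]) go to training, so
    every class with two or more records appears in both partitions.  A
    singleton class goes entirely to training with a warning.
    """
    if not (0.0 < fraction_train < 1.0):
        raise ValueError("fraction_train must lie in (0, 1)")
    if len(record_ids) != len(class_tags):
        raise ValueError("ids and class tags must align")
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    tags = np.asarray(class_tags)
    ids = np.asarray(record_ids, dtype=object)
    for tag in sorted(set(class_tags)):
        members = ids[tags == tag]
        order = rng.permutation(len(members))
        members = members[order]
        if len(members) == 1:
            logger.warning(
                "class %r has a single record; assigned to training", tag
            )
            train.extend(members.tolist())
            continue
        n_train = int(math.floor(fraction_train * len(members) + 0.5))
        n_train = max(1, min(len(members) - 1, n_train))
        if n_train == len(members) - 1 and fraction_train * len(members) > len(members) - 0.5:
            logger.warning(
                "class %r rounding would leave the test partition empty; "
                "kept one record there", tag,
            )
        train.extend(members[:n_train].tolist())
        test.extend(members[n_train:].tolist())
    return train, test


# ---------------------------------------------------------------------------
# Learning curves

@dataclass(frozen=True)
class LearningCurve:
    """Mean train/CV MAE as a function of the included data fraction."""

    fractions: tuple[float, ...]
    train_mae: tuple[float, ...]
    cv_mae: tuple[float, ...]
    k_folds: int = 10

    def __post_init__(self) -> None:
        f = self.fractions
        if not all(0.0 < a <= 1.0 for a in f):
            raise ValueError("fractions must lie in (0, 1]")
        if not all(a < b for a, b in zip(f, f[1:])):
            raise ValueError("fractions must be strictly increasing")
        if not (len(f) == len(self.train_mae) == len(self.cv_mae)):
            raise ValueError("curve arrays must have equal length")


TUNING_FRACTIONS = (0.5, 1.0)
FINAL_FRACTIONS = tuple(np.linspace(0.5, 1.0, 20))


def learning_curve_analysis(
    model,
    X: np.ndarray,
    y: np.ndarray,
    fractions: Sequence[float] = TUNING_FRACTIONS,
    k_folds: int = 10,
    seed: int = 0,
) -> LearningCurve:
    """k-fold learning curve of a regressor over data fractions.

    For each fraction a seeded subsample of the rows is drawn, k-fold CV
    is run on it, and the mean training-fold and validation-fold MAE are
    recorded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    train_mae: list[float] = []
    cv_mae: list[float] = []
    for f in fractions:
        m = int(round(f * n))
        if m < k_folds:
            raise ValueError(
                f"fraction {f} leaves {m} samples, fewer than {k_folds} folds"
            )
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        Xf, yf = X[idx], y[idx]
        kf = KFold(n_splits=k_folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        tr_errs, cv_errs = [], []
        for tr, va in kf.split(Xf):
            est = clone(model)
            est.fit(Xf[tr], yf[tr])
            tr_errs.append(np.mean(np.abs(est.predict(Xf[tr]) - yf[tr])))
            cv_errs.append(np.mean(np.abs(est.predict(Xf[va]) - yf[va])))
        train_mae.append(float(np.mean(tr_errs)))
        cv_mae.append(float(np.mean(cv_errs)))
    return LearningCurve(
        fractions=tuple(float(f) for f in fractions),
        train_mae=tuple(train_mae),
        cv_mae=tuple(cv_mae),
        k_folds=k_folds,
    )


def custom_loss_terms(
    curve: LearningCurve,
    lambda_gap: float = 1.0,
    lambda_slope: float = 1.0,
) -> dict[str, float]:
    """The accuracy term and the two LCA hinge penalties, separately."""
    cv_last = curve.cv_mae[-1]
    tr_last = curve.train_mae[-1]
    cv_first = curve.cv_mae[0]
    return {
        "cv_mae_largest": cv_last,
        "gap_penalty": lambda_gap * max(0.0, cv_last - tr_last),
        "slope_penalty": lambda_slope * max(0.0, cv_last - cv_first),
    }


def custom_loss(
    curve: LearningCurve,
    lambda_gap: float = 1.0,
    lambda_slope: float = 1.0,
) -> float:
    """Accuracy + generalization loss minimised by the search."""
    t = custom_loss_terms(curve, lambda_gap, lambda_slope)
    return t["cv_mae_largest"] + t["gap_penalty"] + t["slope_penalty"]


# ---------------------------------------------------------------------------
# Hyperparameter spaces and the family registry

@dataclass(frozen=True)
class RegressorSpec:
    """A registered model family and its hyperparameter space.

    Space entries are tuples: ``("loguniform", lo, hi)``,
    ``("uniform", lo, hi)``, ``("int", lo, hi)`` or
    ``("choice", (options,))``.
    """

    family_id: str
    space: Mapping[str, tuple]
    builder: Callable[[dict], object]

    def __post_init__(self) -> None:
        if not self.space:
            raise ValueError("hyperparameter space must be nonempty")


def _scaled(est):
    return make_pipeline(StandardScaler(), est)


FAMILY_REGISTRY: dict[str, RegressorSpec] = {}


def register_family(
    family_id: str, space: Mapping[str, tuple], builder: Callable[[dict], object]
) -> None:
    FAMILY_REGISTRY[family_id] = RegressorSpec(family_id, dict(space), builder)


register_family(
    "svr",
    {
        "C": ("loguniform", 1e-2, 1e3),
        "gamma": ("loguniform", 1e-4, 1e1),
        "epsilon": ("loguniform", 1e-4, 1e0),
    },
    lambda p: _scaled(SVR(kernel="rbf", **p)),
)
register_family(
    "nu-svr",
    {
        "C": ("loguniform", 1e-2, 1e3),
        "gamma": ("loguniform", 1e-4, 1e1),
        "nu": ("uniform", 0.05, 0.95),
    },
    lambda p: _scaled(NuSVR(kernel="rbf", **p)),
)
register_family(
    "hist-gradient-boosting",
    {
        "learning_rate": ("loguniform", 1e-2, 0.5),
        "max_iter": ("int", 50, 300),
        "max_leaf_nodes": ("int", 7, 63),
        "l2_regularization": ("loguniform", 1e-8, 1e1),
    },
    lambda p: HistGradientBoostingRegressor(random_state=0, **p),
)
register_family(
    "gradient-boosting",
    {
        "learning_rate": ("loguniform", 1e-2, 0.5),
        "n_estimators": ("int", 50, 300),
        "max_depth": ("int", 2, 6),
        "subsample": ("uniform", 0.5, 1.0),
    },
    lambda p: GradientBoostingRegressor(random_state=0, **p),
)
register_family(
    "mlp",
    {
        "hidden_layer_sizes": ("choice", ((32,), (64,), (64, 32), (128, 64))),
        "alpha": ("loguniform", 1e-6, 1e-1),
        "learning_rate_init": ("loguniform", 1e-4, 1e-1),
    },
    lambda p: _scaled(MLPRegressor(max_iter=800, random_state=0, **p)),
)
register_family(
    "ridge",
    {"alpha": ("loguniform", 1e-6, 1e3)},
    lambda p: _scaled(Ridge(**p)),
)


def build_estimator(family_id: str, params: dict):
    spec = FAMILY_REGISTRY[family_id]
    return spec.builder(dict(params))


# ---------------------------------------------------------------------------
# Samplers (contract: sampler(space, rng, history) -> params dict)
# history is a list of (params, loss) pairs of completed trials.

def _sample_one(kind_spec: tuple, rng: np.random.Generator):
    kind = kind_spec[0]
    if kind == "loguniform":
        lo, hi = kind_spec[1], kind_spec[2]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if kind == "uniform":
        return float(rng.uniform(kind_spec[1], kind_spec[2]))
    if kind == "int":
        return int(rng.integers(kind_spec[1], kind_spec[2] + 1))
    if kind == "choice":
        options = kind_spec[1]
        return options[int(rng.integers(len(options)))]
    raise ValueError(f"unknown space entry {kind_spec!r}")


class RandomSampler:
    """Independent uniform/log-uniform draws from the space."""

    def __call__(self, space, rng, history):
        return {name: _sample_one(spec, rng) for name, spec in space.items()}


class GridSampler:
    """Exhaustive cartesian product over choice-only spaces.

    Cycles deterministically; raises if any dimension is continuous.
    """

    def __init__(self):
        self._grid = None
        self._i = 0

    def __call__(self, space, rng, history):
        if self._grid is None:
            axes = []
            for name, spec in space.items():
                if spec[0] == "choice":
                    axes.append([(name, v) for v in spec[1]])
                elif spec[0] == "int":
                    axes.append(
                        [(name, v) for v in range(spec[1], spec[2] + 1)]
                    )
                else:
                    raise ValueError(
                        f"GridSampler needs discrete dimensions, got {spec!r} "
                        f"for {name!r}"
                    )
            self._grid = [dict(combo) for combo in itertools.product(*axes)]
        params = self._grid[self._i % len(self._grid)]
        self._i += 1
        return params

    @property
    def n_points(self) -> int | None:
        return None if self._grid is None else len(self._grid)


class TPESampler:
    """Lightweight tree-structured-Parzen-style sampler.

    After ``n_startup`` random trials, past trials are split at the
    ``gamma`` loss quantile; candidates are drawn from Gaussian kernels
    centred on the good trials and ranked by the density ratio
    good/bad.  Continuous dimensions work in log space where declared;
    categorical dimensions use add-one category frequencies.
    """

    def __init__(self, n_startup: int = 10, gamma: float = 0.25,
                 n_candidates: int = 24):
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self._fallback = RandomSampler()

    @staticmethod
    def _to_unit(value, spec):
        kind = spec[0]
        if kind == "loguniform":
            lo, hi = np.log(spec[1]), np.log(spec[2])
            return (np.log(value) - lo) / (hi - lo)
        if kind in ("uniform", "int"):
            lo, hi = spec[1], spec[2]
            return (value - lo) / (hi - lo) if hi > lo else 0.5
        return None

    @staticmethod
    def _from_unit(u, spec):
        u = float(np.clip(u, 0.0, 1.0))
        kind = spec[0]
        if kind == "loguniform":
            lo, hi = np.log(spec[1]), np.log(spec[2])
            return float(np.exp(lo + u * (hi - lo)))
        if kind == "uniform":
            return float(spec[1] + u * (spec[2] - spec[1]))
        if kind == "int":
            return int(round(spec[1] + u * (spec[2] - spec[1])))
        raise ValueError(kind)

    def __call__(self, space, rng, history):
        done = [(p, l) for p, l in history if np.isfinite(l)]
        if len(done) < self.n_startup:
            return self._fallback(space, rng, history)
        done.sort(key=lambda t: t[1])
        n_good = max(2, int(math.ceil(self.gamma * len(done))))
        good = [p for p, _ in done[:n_good]]
        bad = [p for p, _ in done[n_good:]] or good
        bw = 0.15
        out = {}
        for name, spec in space.items():
            if spec[0] == "choice":
                options = list(spec[1])
                counts_g = np.array(
                    [1.0 + sum(1 for p in good if p[name] == o)
                     for o in options]
                )
                counts_b = np.array(
                    [1.0 + sum(1 for p in bad if p[name] == o)
                     for o in options]
                )
                score = (counts_g / counts_g.sum()) / (counts_b / counts_b.sum())
                probs = score / score.sum()
                out[name] = options[int(rng.choice(len(options), p=probs))]
                continue
            ug = np.array([self._to_unit(p[name], spec) for p in good])
            ub = np.array([self._to_unit(p[name], spec) for p in bad])

            def mixture_pdf(u, centers):
                z = (u[:, None] - centers[None, :]) / bw
                return np.mean(np.exp(-0.5 * z * z), axis=1) + 1e-12

            cand = rng.normal(
                ug[rng.integers(len(ug), size=self.n_candidates)], bw
            )
            cand = np.clip(cand, 0.0, 1.0)
            ratio = mixture_pdf(cand, ug) / mixture_pdf(cand, ub)
            out[name] = self._from_unit(cand[int(np.argmax(ratio))], spec)
        return out


# ---------------------------------------------------------------------------
# The search itself

@dataclass(frozen=True)
class ModelSearchResult:
    """Outcome of a hyperparameter search for one model family."""

    spec: RegressorSpec
    best_params: dict
    train_metrics: MetricSet
    cv_metrics: MetricSet
    lca: LearningCurve
    penalty: float
    score: float
    seed: int
    n_trials: int = 0
    trial_losses: tuple[float, ...] = ()

    @property
    def family_id(self) -> str:
        return self.spec.family_id


def _cv_predictions(model, X, y, k_folds, seed):
    kf = KFold(n_splits=min(k_folds, len(y)), shuffle=True, random_state=seed)
    pred = np.empty_like(y, dtype=float)
    for tr, va in kf.split(X):
        est = clone(model)
        est.fit(X[tr], y[tr])
        pred[va] = est.predict(X[va])
    return pred


def tune(
    spec: RegressorSpec | str,
    X: np.ndarray,
    y: np.ndarray,
    n_trials: int = 100,
    sampler: Callable | None = None,
    seed: int = 0,
    k_folds: int = 10,
    fractions: Sequence[float] = TUNING_FRACTIONS,
    lambda_gap: float = 1.0,
    lambda_slope: float = 1.0,
) -> ModelSearchResult:
    """Minimise the LCA-penalised loss over hyperparameter trials.

    Each trial draws parameters from the sampler (TPE-style by
    default), builds the family's estimator, runs the tuning learning
    curve (10-fold CV at the requested fractions, folds seeded from the
    root seed plus the trial index) and scores it with
    :func:`custom_loss`.  A failed model fit scores +inf and the search
    continues.  Returns the best trial with pooled-CV and training
    metrics and its learning curve.
    """
    if isinstance(spec, str):
        spec = FAMILY_REGISTRY[spec]
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sampler = sampler or TPESampler()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    history: list[tuple[dict, float]] = []
    best: tuple[float, dict, LearningCurve] | None = None
    for trial in range(n_trials):
        params = sampler(spec.space, rng, history)
        try:
            model = spec.builder(dict(params))
            curve = learning_curve_analysis(
                model, X, y, fractions=fractions, k_folds=k_folds,
                seed=seed + trial + 1,
            )
            loss = custom_loss(curve, lambda_gap, lambda_slope)
        except Exception as exc:  # noqa: BLE001 - any fit failure voids the trial
            logger.warning(
                "trial %d of family %s failed: %s", trial, spec.family_id, exc
            )
            history.append((params, float("inf")))
            continue
        history.append((params, loss))
        if best is None or loss < best[0]:
            best = (loss, dict(params), curve)
    if best is None:
        raise RuntimeError(f"every trial of family {spec.family_id} failed")
    loss, params, curve = best
    model = spec.builder(dict(params))
    fitted = clone(model)
    fitted.fit(X, y)
    train_metrics = compute_metrics(y, fitted.predict(X))
    cv_pred = _cv_predictions(model, X, y, k_folds, seed)
    cv_metrics = compute_metrics(y, cv_pred)
    terms = custom_loss_terms(curve, lambda_gap, lambda_slope)
    return ModelSearchResult(
        spec=spec,
        best_params=params,
        train_metrics=train_metrics,
        cv_metrics=cv_metrics,
        lca=curve,
        penalty=terms["gap_penalty"] + terms["slope_penalty"],
        score=loss,
        seed=seed,
        n_trials=n_trials,
        trial_losses=tuple(l for _, l in history),
    )


def rank_models(results: Iterable[ModelSearchResult]) -> list[ModelSearchResult]:
    """Results sorted by ascending search score; ties break on family id."""
    results = list(results)
    if not results:
        raise ValueError("no search results to rank")
    return sorted(results, key=lambda r: (r.score, r.family_id))


def ranking_report(results: Iterable[ModelSearchResult],
                   which: str = "cv") -> str:
    """Human-readable ranking with (RMSD, MAPE%) pairs per family."""
    ranked = rank_models(results)
    lines = [f"{'family':<24}{'score':>10}{'RMSD':>9}{'MAPE%':>9}"]
    for r in ranked:
        m = r.cv_metrics if which == "cv" else r.train_metrics
        lines.append(
            f"{r.family_id:<24}{r.score:>10.4f}{m.rmsd:>9.3f}"
            f"{m.mape_percent:>9.2f}"
        )
    return "\n".join(lines)
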