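"""The two wrapped optimization problems and the framework driver.

Feature selection (tabular): each candidate vector decodes to a keep/drop
mask; the kept columns are scored by the best of a small per-model
hyperparameter grid under stratified 5-fold cross-validation with
fold-fit scalers, and the fitness is ``1 - best mean CV accuracy`` plus a
microscopic kept-feature penalty that breaks exact-accuracy ties toward
smaller subsets.

Hyperparameter optimization (images): each candidate decodes to a 15-cell
trial configuration; a trainer builds the classifier with the decoded
dropout/loss/optimizer/learn-ratio, applies the decoded scaler and
augmentation, trains 5 epochs on the stratified 80% split, and the fitness
is the held-out loss.  The trainer is a pluggable contract: pretrained
CNN backbone names are accepted but require a user-supplied trainer; the
built-in ``tiny-test`` backbone is a small numpy softmax network that
exercises every decoded hyperparameter at desk scale.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

from . import gto_core
from .gto_core import GTOParams, OptimizationResult
from .metrics import (
    ConfusionCounts,
    MetricReport,
    auc_from_scores,
    compute_metrics,
    confusion_from_predictions,
    cosine_similarity_metric,
)
from .preprocessing import FittedScaler, apply_augmentation, impute_missing, label_encode
from .solution_mapping import (
    FeatureMask,
    TrialConfig,
    default_hyperparameter_space,
    extract_data_subset,
    map_solution_to_feature_mask,
    map_solution_to_trial_config,
)

__all__ = [
    "GridSpec",
    "FSProblem",
    "TLProblem",
    "RunReport",
    "default_grid",
    "fitness_feature_selection",
    "fitness_tl_hpo",
    "evaluate_mask",
    "evaluate_config",
    "run_framework",
    "TinyTestTrainer",
    "PRETRAINED_BACKBONES",
]

PRETRAINED_BACKBONES = (
    "DenseNet169",
    "DenseNet201",
    "MobileNet",
    "MobileNetV2",
    "MobileNetV3Small",
    "MobileNetV3Large",
)

#: Tie-break weight: prefers smaller subsets only among equal-accuracy masks.
_FEATURE_PENALTY = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """Per-model hyperparameter grid searched inside every fitness call."""

    model_kind: str
    points: tuple[dict, ...]


def default_grid(model_kind: str) -> GridSpec:
    """DT/ET: criterion x splitter; LGBM: learning rate, 300 estimators."""
    if model_kind in ("DT", "ET"):
        points = tuple(
            {"criterion": c, "splitter": s}
            for c in ("gini", "entropy")
            for s in ("best", "random")
        )
    elif model_kind == "LGBM":
        points = tuple({"learning_rate": lr} for lr in (0.01, 0.1, 1.0))
    else:
        raise ValueError(f"unknown model kind {model_kind!r}; pick DT, ET, or LGBM")
    return GridSpec(model_kind=model_kind, points=points)


def _make_model(model_kind: str, point: dict, seed: int):
    if model_kind == "DT":
        return DecisionTreeClassifier(random_state=seed, **point)
    if model_kind == "ET":
        return ExtraTreeClassifier(random_state=seed, **point)
    if model_kind == "LGBM":
        return LGBMClassifier(
            n_estimators=300, random_state=seed, n_jobs=1, verbose=-1, **point
        )
    raise ValueError(f"unknown model kind {model_kind!r}")


@dataclass
class FSProblem:
    """A wrapper feature-selection problem over a screening table.

    ``scaler`` names the column-scaling transform fit on each training fold;
    ``class_column`` is excluded from selection.  ``result_eligible=False``
    removes the ``result`` column (a deterministic function of the item
    scores in AQ-10-style data) from the selectable set.
    """

    table: pd.DataFrame
    model_kind: str = "DT"
    folds: int = 5
    scaler: str = "standardization"
    seed: int = 0
    class_column: str = "class"
    result_eligible: bool = True
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = default_grid(self.model_kind)
        work = impute_missing(self.table)
        if not self.result_eligible and "result" in work.columns:
            work = work.drop(columns=["result"])
        encoded, self.category_maps = label_encode(
            work, [c for c in work.columns
                   if work[c].dtype == object and c != self.class_column]
        )
        self.feature_columns = [c for c in encoded.columns if c != self.class_column]
        self._X = encoded[self.feature_columns].to_numpy(dtype=float)
        self._y = encoded[self.class_column].to_numpy()
        self._cache: dict[tuple, dict] = {}

    @property
    def dim(self) -> int:
        return len(self.feature_columns)


def _cv_accuracy(problem: FSProblem, X: np.ndarray) -> tuple[float, dict, dict]:
    """Grid-searched stratified CV on the given feature block.

    Returns (best mean accuracy, winning grid point, out-of-fold artifacts
    of the winner: predictions and positive-class scores).
    """
    y = problem._y
    skf = StratifiedKFold(
        n_splits=problem.folds, shuffle=True, random_state=problem.seed
    )
    splits = list(skf.split(X, y))
    best = (-1.0, None, None)
    for point in problem.grid.points:
        preds = np.empty(len(y), dtype=object)
        scores = np.zeros(len(y))
        correct = 0
        for tr, te in splits:
            Xtr, Xte = X[tr], X[te]
            sc = FittedScaler(problem.scaler)
            Xtr = sc.fit_transform(Xtr)
            Xte = sc.transform(Xte)
            model = _make_model(problem.model_kind, point, problem.seed)
            model.fit(Xtr, y[tr])
            p = model.predict(Xte)
            preds[te] = p
            pos = list(model.classes_).index(model.classes_[-1])
            scores[te] = model.predict_proba(Xte)[:, pos]
            correct += int(np.sum(p == y[te]))
        acc = correct / len(y)
        if acc > best[0]:
            best = (acc, point, {"preds": preds, "scores": scores})
    return best


def evaluate_mask(problem: FSProblem, mask: FeatureMask) -> dict:
    """Full evaluation of one mask: grid-searched CV accuracy, the winning
    grid point, the out-of-fold metric report, and the elapsed wall time."""
    kept = [i for i, f in enumerate(mask.flags) if f]
    t0 = time.perf_counter()
    acc, winner, oof = _cv_accuracy(problem, problem._X[:, kept])
    elapsed = time.perf_counter() - t0
    y = problem._y
    positive = sorted(np.unique(y))[-1]  # "YES" under the screening schema
    counts = confusion_from_predictions(y, np.asarray(list(oof["preds"])), positive)
    try:
        auc = auc_from_scores(y, oof["scores"], positive_label=positive)
    except ValueError:
        auc = None
    report = compute_metrics(counts, auc=auc)
    return {
        "accuracy": acc,
        "grid_winner": winner,
        "counts": counts,
        "report": report,
        "elapsed_s": elapsed,
        "n_kept": mask.n_kept,
    }


def fitness_feature_selection(solution, problem: FSProblem) -> float:
    """Decode, extract, grid-search, cross-validate: ``1 - best CV accuracy``
    plus a tiny kept-feature tie-break penalty.  Memoized on the mask."""
    mask = map_solution_to_feature_mask(np.asarray(solution))
    key = mask.flags
    hit = problem._cache.get(key)
    if hit is None:
        kept = [i for i, f in enumerate(key) if f]
        acc, winner, _ = _cv_accuracy(problem, problem._X[:, kept])
        hit = {"accuracy": acc, "grid_winner": winner}
        problem._cache[key] = hit
    return (1.0 - hit["accuracy"]) + _FEATURE_PENALTY * mask.n_kept / problem.dim


# --------------------------------------------------------------------------
# Transfer-learning problem


@dataclass
class TLProblem:
    """Hyperparameter optimization for a two-class image classifier.

    ``images`` is an (N, H, W, 3) float array in [0, 1] with ``labels`` of
    length N; the split is stratified 80/20.  ``trainer`` implements the
    training contract ``trainer(config, Xtr, ytr, Xte, yte, seed) -> dict``
    with keys ``loss``, ``accuracy``, ``probs``; it defaults to the built-in
    tiny-test network for the ``tiny-test`` backbone and must be supplied
    for the pretrained CNN backbone names.
    """

    images: np.ndarray
    labels: np.ndarray
    backbone: str = "tiny-test"
    epochs: int = 5
    train_fraction: float = 0.8
    seed: int = 0
    trainer: Callable | None = None

    def __post_init__(self) -> None:
        if self.trainer is None:
            if self.backbone == "tiny-test":
                self.trainer = TinyTestTrainer(epochs=self.epochs)
            elif self.backbone in PRETRAINED_BACKBONES:
                raise ValueError(
                    f"backbone {self.backbone!r} needs a user-supplied trainer "
                    "(the built-in trainer only implements 'tiny-test')"
                )
            else:
                raise ValueError(f"unknown backbone {self.backbone!r}")
        self._split_cache: tuple | None = None
        self._cache: dict[tuple, dict] = {}

    def split(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Deterministic stratified 80/20 split (seeded by the problem)."""
        if self._split_cache is None:
            rng = np.random.default_rng(self.seed)
            y = np.asarray(self.labels)
            train_idx = []
            test_idx = []
            for cls in np.unique(y):
                idx = np.nonzero(y == cls)[0]
                idx = rng.permutation(idx)
                cut = int(round(self.train_fraction * len(idx)))
                train_idx.extend(idx[:cut])
                test_idx.extend(idx[cut:])
            tr = np.sort(train_idx)
            te = np.sort(test_idx)
            self._split_cache = (self.images[tr], y[tr], self.images[te], y[te])
        return self._split_cache


def _config_key(config: TrialConfig) -> tuple:
    return tuple(sorted((k, str(v)) for k, v in config.values.items()))


def fitness_tl_hpo(solution, problem: TLProblem) -> float:
    """Decode the 15-cell vector and train under the decoded configuration.

    Fitness is the held-out loss; a trainer failure yields +inf so the
    optimizer simply rejects the candidate.  Memoized on the decoded
    configuration (inert augmentation cells do not enter the key, so
    configurations differing only in unused cells share one evaluation).
    """
    config = map_solution_to_trial_config(np.asarray(solution))
    key = _config_key(config)
    hit = problem._cache.get(key)
    if hit is None:
        Xtr, ytr, Xte, yte = problem.split()
        try:
            hit = problem.trainer(config, Xtr, ytr, Xte, yte, problem.seed)
        except Exception as exc:
            hit = {"loss": np.inf, "accuracy": 0.0, "error": repr(exc)}
        problem._cache[key] = hit
    return float(hit["loss"])


# --------------------------------------------------------------------------
# Built-in tiny-test trainer: a small numpy softmax network


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grad(name: str, probs: np.ndarray, onehot: np.ndarray, logits: np.ndarray):
    """Mean loss and its gradient w.r.t. the logits for the decoded loss name.

    Hinge-family losses act on the softmax margins; probability-based losses
    act on the clipped softmax outputs.  All gradients are propagated through
    the softmax Jacobian.
    """
    n = probs.shape[0]
    eps = 1e-9
    p = np.clip(probs, eps, 1.0)
    if name == "categorical_crossentropy":
        loss = -np.sum(onehot * np.log(p)) / n
        dlogits = (probs - onehot) / n
        return loss, dlogits
    if name == "kl_divergence":
        # identical to crossentropy up to the (zero) entropy of one-hot truth
        loss = np.sum(onehot * np.log(np.clip(onehot, eps, 1.0) / p)) / n
        dlogits = (probs - onehot) / n
        return loss, dlogits
    if name == "poisson":
        loss = np.sum(p - onehot * np.log(p)) / n
        dp = (1.0 - onehot / p) / n
    elif name in ("categorical_hinge", "hinge", "squared_hinge"):
        pos = np.sum(onehot * probs, axis=1, keepdims=True)
        neg = np.max((1.0 - onehot) * probs, axis=1, keepdims=True)
        margin = 1.0 + neg - pos
        active = margin > 0
        neg_mask = ((1.0 - onehot) * probs == neg) & (onehot == 0)
        if name == "squared_hinge":
            loss = np.sum(np.maximum(margin, 0.0) ** 2) / n
            coef = 2.0 * np.maximum(margin, 0.0) * active
        else:  # hinge and categorical hinge coincide for one-hot truth
            loss = np.sum(np.maximum(margin, 0.0)) / n
            coef = 1.0 * active
        dp = coef * (neg_mask.astype(float) - onehot) / n
    else:
        raise ValueError(f"unknown loss {name!r}")
    # chain rule through softmax: dL/dz = P * (dp - sum(dp * P))
    inner = np.sum(dp * probs, axis=1, keepdims=True)
    dlogits = probs * (dp - inner)
    return loss, dlogits


class _Optimizer:
    """First-order update rules for the eleven decoded optimizer names.

    Each name maps onto a genuine update family: the SGD pair, the
    Adam/NAdam/AdaMax/AMSGrad family, RMSProp (plain and centered),
    AdaGrad, AdaDelta, and FTRL (implemented in its accumulator form
    without regularization, which reduces to per-coordinate AdaGrad).
    """

    def __init__(self, name: str, lr: float = 0.05):
        self.name = name
        self.lr = lr
        self.state: dict[int, dict] = {}

    def _st(self, i: int, shape) -> dict:
        if i not in self.state:
            self.state[i] = {
                "m": np.zeros(shape), "v": np.zeros(shape),
                "vhat": np.zeros(shape), "g2": np.zeros(shape),
                "d2": np.zeros(shape), "mg": np.zeros(shape), "t": 0,
            }
        return self.state[i]

    def update(self, i: int, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        s = self._st(i, param.shape)
        s["t"] += 1
        t, lr, eps = s["t"], self.lr, 1e-8
        name = self.name
        if name == "sgd":
            return param - lr * grad
        if name == "sgd_nesterov":
            mu = 0.9
            s["m"] = mu * s["m"] - lr * grad
            return param + mu * s["m"] - lr * grad
        if name in ("adam", "nadam", "adam_amsgrad", "adamax"):
            b1, b2 = 0.9, 0.999
            s["m"] = b1 * s["m"] + (1 - b1) * grad
            if name == "adamax":
                s["v"] = np.maximum(b2 * s["v"], np.abs(grad))
                mhat = s["m"] / (1 - b1 ** t)
                return param - lr * mhat / (s["v"] + eps)
            s["v"] = b2 * s["v"] + (1 - b2) * grad ** 2
            mhat = s["m"] / (1 - b1 ** t)
            vhat = s["v"] / (1 - b2 ** t)
            if name == "adam_amsgrad":
                s["vhat"] = np.maximum(s["vhat"], vhat)
                vhat = s["vhat"]
            if name == "nadam":
                mhat = b1 * mhat + (1 - b1) * grad / (1 - b1 ** t)
            return param - lr * mhat / (np.sqrt(vhat) + eps)
        if name in ("rmsprop", "rmsprop_centered"):
            rho = 0.9
            s["v"] = rho * s["v"] + (1 - rho) * grad ** 2
            denom = s["v"]
            if name == "rmsprop_centered":
                s["mg"] = rho * s["mg"] + (1 - rho) * grad
                denom = s["v"] - s["mg"] ** 2
            return param - lr * grad / (np.sqrt(np.maximum(denom, 0)) + eps)
        if name in ("adagrad", "ftrl"):
            s["g2"] += grad ** 2
            return param - lr * grad / (np.sqrt(s["g2"]) + eps)
        if name == "adadelta":
            rho = 0.95
            s["v"] = rho * s["v"] + (1 - rho) * grad ** 2
            step = np.sqrt(s["d2"] + eps) / np.sqrt(s["v"] + eps) * grad
            s["d2"] = rho * s["d2"] + (1 - rho) * step ** 2
            return param - step  # adadelta carries its own scale
        raise ValueError(f"unknown optimizer {self.name!r}")


class TinyTestTrainer:
    """Desk-scale trainer implementing the TL training contract.

    The "backbone" is one dense hidden layer with fixed random weights and a
    ReLU; the head is a softmax layer.  The decoded TL learn ratio is the
    percentage of backbone layers made trainable (one layer here, so a ratio
    >= 50% unfreezes it).  Dropout is applied to the hidden activations
    during training; the decoded scaler is fit globally on the training
    pixels; augmentation redraws each training image every epoch when the
    DA flag is on.
    """

    def __init__(self, hidden: int = 32, epochs: int = 5):
        self.hidden = hidden
        self.epochs = epochs

    def __call__(self, config: TrialConfig, Xtr, ytr, Xte, yte, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        classes = np.unique(np.concatenate([np.asarray(ytr), np.asarray(yte)]))
        n_classes = len(classes)

        scaler = FittedScaler(config["scaler"])
        scaler.fit(np.asarray(Xtr, dtype=float).reshape(-1, 1))

        def features(batch: np.ndarray) -> np.ndarray:
            flat = batch.reshape(len(batch), -1)
            return scaler.transform(flat.reshape(-1, 1)).reshape(flat.shape)

        d = int(np.prod(np.asarray(Xtr).shape[1:]))
        W1 = rng.standard_normal((d, self.hidden)) / np.sqrt(d)
        b1 = np.zeros(self.hidden)
        W2 = rng.standard_normal((self.hidden, n_classes)) / np.sqrt(self.hidden)
        b2 = np.zeros(n_classes)
        backbone_trainable = config["tl_learn_ratio"] >= 50

        opt = _Optimizer(config["optimizer"])
        dropout = config["dropout"]
        batch_size = int(config["batch_size"])
        Ttr = _one_hot(np.asarray(ytr), classes)

        for _ in range(self.epochs):
            if config.use_da:
                Xe = np.stack(
                    [apply_augmentation(img, config, rng) for img in Xtr]
                )
            else:
                Xe = np.asarray(Xtr, dtype=float)
            Fe = features(Xe)
            order = rng.permutation(len(Fe))
            for start in range(0, len(Fe), batch_size):
                idx = order[start:start + batch_size]
                xb, tb = Fe[idx], Ttr[idx]
                h_pre = xb @ W1 + b1
                h = np.maximum(h_pre, 0.0)
                if dropout > 0:
                    keep = rng.random(h.shape) >= dropout
                    h = h * keep / (1.0 - dropout)
                logits = h @ W2 + b2
                probs = _softmax(logits)
                _, dlogits = _loss_and_grad(config["loss"], probs, tb, logits)
                gW2 = h.T @ dlogits
                gb2 = dlogits.sum(axis=0)
                W2 = opt.update(2, W2, gW2)
                b2 = opt.update(3, b2, gb2)
                if backbone_trainable:
                    dh = dlogits @ W2.T
                    if dropout > 0:
                        dh = dh * keep / (1.0 - dropout)
                    dh = dh * (h_pre > 0)
                    W1 = opt.update(0, W1, xb.T @ dh)
                    b1 = opt.update(1, b1, dh.sum(axis=0))

        def predict(batch: np.ndarray) -> np.ndarray:
            F = features(np.asarray(batch, dtype=float))
            h = np.maximum(F @ W1 + b1, 0.0)
            return _softmax(h @ W2 + b2)

        probs_te = predict(Xte)
        Tte = _one_hot(np.asarray(yte), classes)
        loss, _ = _loss_and_grad(config["loss"], probs_te, Tte, None)
        pred = classes[np.argmax(probs_te, axis=1)]
        accuracy = float(np.mean(pred == np.asarray(yte)))
        return {
            "loss": float(loss),
            "accuracy": accuracy,
            "probs": probs_te,
            "classes": classes,
            "predictions": pred,
        }


# --------------------------------------------------------------------------
# Framework driver


@dataclass
class RunReport:
    """Everything one optimization run produced."""

    problem_kind: str
    best_score: float
    best_solution: list[float]
    decoded: dict[str, Any]
    grid_winner: dict | None
    report: MetricReport
    counts: ConfusionCounts | None
    history: list[float]
    evaluations: int
    elapsed_s: float
    seed: int | None
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "problem_kind": self.problem_kind,
            "best_score": self.best_score,
            "best_solution": list(map(float, self.best_solution)),
            "decoded": self.decoded,
            "grid_winner": self.grid_winner,
            "metrics_percent": self.report.as_percentages(),
            "metrics_formatted": self.report.format_rows(),
            "degenerate_metrics": self.report.degenerate,
            "history": list(map(float, self.history)),
            "evaluations": self.evaluations,
            "elapsed_s": self.elapsed_s,
            "seed": self.seed,
        }
        if self.counts is not None:
            d["confusion"] = {
                "TP": self.counts.TP, "TN": self.counts.TN,
                "FP": self.counts.FP, "FN": self.counts.FN,
            }
        d.update(self.extras)
        return d


def run_framework(problem, params: GTOParams) -> RunReport:
    """Drive the optimizer over the given problem and refit the winner.

    For feature selection the final report re-evaluates the winning mask
    under the full grid-searched CV protocol; for the image problem the
    winning configuration is retrained and scored on the held-out 20%.
    """
    t0 = time.perf_counter()
    if isinstance(problem, FSProblem):
        result = gto_core.optimize(
            lambda x: fitness_feature_selection(x, problem),
            params, D=problem.dim, LB=0.0, UB=1.0,
        )
        mask = map_solution_to_feature_mask(result.best_solution)
        final = evaluate_mask(problem, mask)
        decoded = {
            "mask": mask.to_string(),
            "kept_columns": [
                c for c, f in zip(problem.feature_columns, mask.flags) if f
            ],
            "n_kept": mask.n_kept,
            "scaler": problem.scaler,
            "model_kind": problem.model_kind,
        }
        return RunReport(
            problem_kind="feature-selection",
            best_score=result.best_score,
            best_solution=result.best_solution.tolist(),
            decoded=decoded,
            grid_winner=final["grid_winner"],
            report=final["report"],
            counts=final["counts"],
            history=result.history,
            evaluations=result.evaluations,
            elapsed_s=time.perf_counter() - t0,
            seed=params.seed,
            extras={"cv_accuracy": final["accuracy"],
                    "final_eval_elapsed_s": final["elapsed_s"]},
        )
    if isinstance(problem, TLProblem):
        result = gto_core.optimize(
            lambda x: fitness_tl_hpo(x, problem),
            params, D=default_hyperparameter_space().dim, LB=0.0, UB=1.0,
        )
        config = map_solution_to_trial_config(result.best_solution)
        final = evaluate_config(problem, config)
        return RunReport(
            problem_kind="tl-hpo",
            best_score=result.best_score,
            best_solution=result.best_solution.tolist(),
            decoded=config.to_record(),
            grid_winner=None,
            report=final["report"],
            counts=final["counts"],
            history=result.history,
            evaluations=result.evaluations,
            elapsed_s=time.perf_counter() - t0,
            seed=params.seed,
            extras={
                "holdout_loss": final["loss"],
                "holdout_accuracy": final["accuracy"],
                "cosine_similarity": final["cosine_similarity"],
            },
        )
    raise TypeError(f"unsupported problem type {type(problem).__name__}")


def evaluate_config(problem: TLProblem, config: TrialConfig) -> dict:
    """Train once under ``config`` and assemble the held-out metric report."""
    Xtr, ytr, Xte, yte = problem.split()
    out = problem.trainer(config, Xtr, ytr, Xte, yte, problem.seed)
    classes = out["classes"]
    positive = classes[-1]
    counts = confusion_from_predictions(yte, out["predictions"], positive)
    pos_col = list(classes).index(positive)
    try:
        auc = auc_from_scores(yte, out["probs"][:, pos_col], positive_label=positive)
    except ValueError:
        auc = None
    report = compute_metrics(counts, auc=auc)
    cos, _ = cosine_similarity_metric(_one_hot(np.asarray(yte), classes), out["probs"])
    return {
        "loss": out["loss"],
        "accuracy": out["accuracy"],
        "counts": counts,
        "report": report,
        "cosine_similarity": cos,
    }
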