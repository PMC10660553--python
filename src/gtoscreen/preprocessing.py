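"""Tabular and image pre-processing.

Tabular: question-mark imputation, label encoding of categorical attributes,
and the five column-scaling transforms (max-normalization, standardization,
min-max, max-abs, and quartile-based robust scaling).  Image: bilinear
resizing to a uniform 128x128x3 shape and randomized label-preserving
augmentation (rotation, shifts, shear, zoom, flips, brightness).

Scaling formulas, as applied per column/record x:

==================  =============================
normalization       x / max(x)
standardization     (x - mean) / sigma  (population sigma)
min-max             (x - min) / (max - min)
max-abs             x / |max(x)|
robust              (x - Q1) / (Q3 - Q1)
==================  =============================

Note the robust transform centers on the first quartile (not the median) —
this matches the formula the framework defines.  Quartiles use linear
interpolation.  Degenerate denominators are guarded: kinds 2/3/5 return
all zeros on constant input, kinds 1/4 fall back to the sign pattern.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "SCALER_KINDS",
    "MISSING_MARKER",
    "impute_missing",
    "label_encode",
    "invert_label_encoding",
    "apply_scaler",
    "scale_table",
    "resize_image",
    "apply_augmentation",
    "IMAGE_SIZE",
]

SCALER_KINDS = ("normalization", "standardization", "min-max", "max-abs", "robust")
MISSING_MARKER = "?"
IMAGE_SIZE = (128, 128, 3)


def impute_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Replace every ``"?"`` cell (an unanswered entry) with 0.

    Row and column counts are unchanged.  Numeric-looking columns that held
    "?" markers are cast back to numeric after substitution.
    """
    out = table.copy()
    for col in out.columns:
        if out[col].dtype == object:
            mask = out[col] == MISSING_MARKER
            if mask.any():
                out.loc[mask, col] = 0
                non_missing = out.loc[~mask, col]
                try:
                    pd.to_numeric(non_missing)
                except (ValueError, TypeError):
                    pass
                else:
                    out[col] = pd.to_numeric(out[col])
    return out


def label_encode(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, dict[int, object]]]:
    """Replace categorical columns by integer codes; return inversion maps.

    Categories are ordered lexicographically.  A column that carries the
    imputed-missing sentinel 0 keeps 0 reserved for it and codes its real
    categories from 1 upward; a complete column codes from 0 upward.
    """
    out = table.copy()
    maps: dict[str, dict[int, object]] = {}
    if columns is None:
        columns = [c for c in out.columns if out[c].dtype == object]
    for col in columns:
        values = out[col]
        has_missing = (values == 0).any() or (values == MISSING_MARKER).any()
        cats = sorted(
            {v for v in values if v != 0 and v != MISSING_MARKER}, key=str
        )
        start = 1 if has_missing else 0
        code_of = {c: i + start for i, c in enumerate(cats)}
        if has_missing:
            code_of[0] = 0
            code_of[MISSING_MARKER] = 0
        try:
            out[col] = values.map(code_of).astype(int)
        except (TypeError, ValueError) as exc:
            unseen = sorted({str(v) for v in values if v not in code_of})
            raise ValueError(
                f"cannot encode column {col!r}: unmapped value(s) {unseen}"
            ) from exc
        maps[col] = {v: k for k, v in code_of.items() if k != MISSING_MARKER}
    return out, maps


def invert_label_encoding(
    table: pd.DataFrame, maps: Mapping[str, Mapping[int, object]]
) -> pd.DataFrame:
    """Map integer codes back to the original categories."""
    out = table.copy()
    for col, inv in maps.items():
        out[col] = out[col].map(dict(inv))
    return out


def apply_scaler(column, kind: str, quantile_method: str = "linear") -> np.ndarray:
    """Scale one numeric vector by the named transform (see module docstring)."""
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("cannot scale an empty column")
    if kind not in SCALER_KINDS:
        raise ValueError(f"unknown scaler kind {kind!r}; pick one of {SCALER_KINDS}")

    if kind == "normalization":
        denom = x.max()
        return x / denom if denom != 0 else np.sign(x)
    if kind == "standardization":
        sigma = x.std()  # population sigma, no Bessel correction
        return (x - x.mean()) / sigma if sigma != 0 else np.zeros_like(x)
    if kind == "min-max":
        span = x.max() - x.min()
        return (x - x.min()) / span if span != 0 else np.zeros_like(x)
    if kind == "max-abs":
        denom = abs(x.max())
        return x / denom if denom != 0 else np.sign(x)
    # robust: first-quartile centering, inter-quartile scaling
    q1, q3 = np.quantile(x, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    return (x - q1) / iqr if iqr != 0 else np.zeros_like(x)


class FittedScaler:
    """A scaler fit on training data and applied to held-out data.

    Fitting records the training statistics (max, mean/sigma, min/max,
    quartiles) so held-out folds are transformed without leakage.
    """

    def __init__(self, kind: str, quantile_method: str = "linear"):
        if kind not in SCALER_KINDS:
            raise ValueError(f"unknown scaler kind {kind!r}")
        self.kind = kind
        self.quantile_method = quantile_method
        self._stats: tuple | None = None

    def fit(self, X) -> "FittedScaler":
        X = np.asarray(X, dtype=float)
        k = self.kind
        if k == "normalization":
            self._stats = (X.max(axis=0),)
        elif k == "standardization":
            self._stats = (X.mean(axis=0), X.std(axis=0))
        elif k == "min-max":
            self._stats = (X.min(axis=0), X.max(axis=0))
        elif k == "max-abs":
            self._stats = (np.abs(X.max(axis=0)),)
        else:
            q1, q3 = np.quantile(X, [0.25, 0.75], axis=0, method=self.quantile_method)
            self._stats = (q1, q3)
        return self

    def transform(self, X) -> np.ndarray:
        if self._stats is None:
            raise RuntimeError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        k = self.kind
        with np.errstate(divide="ignore", invalid="ignore"):
            if k == "normalization":
                (mx,) = self._stats
                out = np.where(mx != 0, X / mx, np.sign(X))
            elif k == "standardization":
                mu, sigma = self._stats
                out = np.where(sigma != 0, (X - mu) / np.where(sigma != 0, sigma, 1), 0.0)
            elif k == "min-max":
                mn, mx = self._stats
                span = mx - mn
                out = np.where(span != 0, (X - mn) / np.where(span != 0, span, 1), 0.0)
            elif k == "max-abs":
                (mx,) = self._stats
                out = np.where(mx != 0, X / mx, np.sign(X))
            else:
                q1, q3 = self._stats
                iqr = q3 - q1
                out = np.where(iqr != 0, (X - q1) / np.where(iqr != 0, iqr, 1), 0.0)
        return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


def scale_table(X_train, X_test, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Fit the named scaler on the training block, apply to both blocks."""
    sc = FittedScaler(kind)
    return sc.fit_transform(X_train), sc.transform(X_test)


def resize_image(image: np.ndarray) -> np.ndarray:
    """Bilinear-resize to 128x128 and replicate grayscale to 3 channels.

    Output is float64.  An image already at the target shape is returned
    unchanged (as a copy), so repeated resizing is idempotent.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D pixel array, got shape {image.shape}")
    if image.shape[2] == 1:
        image = np.repeat(image, 3, axis=2)
    if image.shape[2] != 3:
        raise ValueError(f"expected 1 or 3 channels, got {image.shape[2]}")
    image = image.astype(float)
    if image.shape[:2] == IMAGE_SIZE[:2]:
        return image.copy()
    return resize(
        image, IMAGE_SIZE[:2], order=1, preserve_range=True,
        anti_aliasing=image.shape[0] > IMAGE_SIZE[0],
    )


def apply_augmentation(image: np.ndarray, config, rng: np.random.Generator) -> np.ndarray:
    """Apply the decoded augmentation settings to one image.

    Applies in order: rotation (uniform in +/- the decoded maximum, degrees),
    width/height shift (uniform fractions of the image size), shear, zoom,
    deterministic horizontal/vertical flips when their flags decode to Yes,
    and a brightness multiplier drawn uniformly from the decoded range.
    Pixel values are assumed in [0, 1] and are clamped there after the
    brightness step.  A config with the DA flag off is the identity.
    """
    image = np.asarray(image, dtype=float)
    if not config.use_da:
        return image.copy()

    h, w = image.shape[:2]
    angle = np.deg2rad(rng.uniform(-config["rotation"], config["rotation"]))
    dx = rng.uniform(-config["width_shift"], config["width_shift"]) * w
    dy = rng.uniform(-config["height_shift"], config["height_shift"]) * h
    shear = rng.uniform(-config["shear"], config["shear"])
    zoom = rng.uniform(1.0 - config["zoom"], 1.0 + config["zoom"])

    out = image
    if angle != 0 or dx != 0 or dy != 0 or shear != 0 or zoom != 1.0:
        center = np.array([w, h]) / 2.0 - 0.5
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=angle, shear=shear, scale=(zoom, zoom))
            + AffineTransform(translation=center + np.array([dx, dy]))
        )
        out = warp(out, tf.inverse, order=1, mode="edge", preserve_range=True)
    if config["horizontal_flip"] == "Yes":
        out = out[:, ::-1]
    if config["vertical_flip"] == "Yes":
        out = out[::-1, :]
    lo, hi = config["brightness"]
    m = rng.uniform(lo, hi)
    if m != 1.0:
        out = np.clip(out * m, 0.0, 1.0)
    return np.ascontiguousarray(out)
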