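"""Decoding real-valued solution vectors into search-space configurations.

The optimizer works on vectors of floats in [0, 1].  Two decodings connect
those vectors to the two wrapped problems:

* a 15-cell hyperparameter vector for the transfer-learning problem, where
  each discrete cell is decoded by the ceiling range-index rule
  ``index = ceil(value * n_options)`` (1-based, clamped to 1 at value 0) and
  each continuous cell by linear interpolation over its interval; and
* a keep/drop feature mask for the tabular problem, where a cell keeps its
  column iff its value >= 0.5 (with an argmax fallback so the mask is never
  empty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RangeSpec",
    "HyperparameterSpace",
    "TrialConfig",
    "FeatureMask",
    "default_hyperparameter_space",
    "map_cell_to_range_index",
    "map_cell_to_continuous",
    "map_solution_to_trial_config",
    "map_solution_to_feature_mask",
    "extract_data_subset",
    "LOSSES",
    "OPTIMIZERS",
    "SCALERS",
    "BATCH_SIZES",
    "TL_LEARN_RATIOS",
    "ROTATIONS",
    "FLAGS",
]

# Discrete option lists of the 15-cell transfer-learning search space.
LOSSES = (
    "categorical_crossentropy",
    "poisson",
    "kl_divergence",
    "categorical_hinge",
    "squared_hinge",
    "hinge",
)
OPTIMIZERS = (
    "adam",
    "nadam",
    "adamax",
    "adadelta",
    "adagrad",
    "rmsprop",
    "ftrl",
    "sgd",
    "sgd_nesterov",
    "rmsprop_centered",
    "adam_amsgrad",
)
SCALERS = ("normalization", "standardization", "min-max", "max-abs", "robust")
BATCH_SIZES = tuple(range(4, 49, 4))  # 4, 8, ..., 48 (12 options)
TL_LEARN_RATIOS = tuple(range(1, 101))  # percent of backbone made trainable
ROTATIONS = tuple(range(0, 46))  # degrees, 0..45
FLAGS = ("No", "Yes")


@dataclass(frozen=True)
class RangeSpec:
    """One search-space cell: a discrete option list, an interval, or a flag."""

    name: str
    kind: str  # "discrete" | "continuous" | "flag"
    options: tuple = ()
    lo: float = 0.0
    hi: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous", "flag"):
            raise ValueError(f"unknown range kind {self.kind!r}")
        if self.kind in ("discrete", "flag") and len(self.options) == 0:
            raise ValueError(f"range {self.name!r} has an empty option list")
        if self.kind == "flag" and len(self.options) != 2:
            raise ValueError(f"flag range {self.name!r} needs exactly two options")
        if self.kind == "continuous" and self.lo > self.hi:
            raise ValueError(f"range {self.name!r} has lo > hi")


@dataclass(frozen=True)
class HyperparameterSpace:
    """The ordered 15-cell transfer-learning search space."""

    cells: tuple[RangeSpec, ...]

    def __post_init__(self) -> None:
        if len(self.cells) != 15:
            raise ValueError(f"expected 15 cells, got {len(self.cells)}")

    @property
    def dim(self) -> int:
        return len(self.cells)


def default_hyperparameter_space() -> HyperparameterSpace:
    """Cells 1-15: loss, batch size, dropout, TL learn ratio, optimizer,
    scaler, DA flag, then the eight augmentation sub-cells."""
    return HyperparameterSpace(
        cells=(
            RangeSpec("loss", "discrete", options=LOSSES),
            RangeSpec("batch_size", "discrete", options=BATCH_SIZES),
            RangeSpec("dropout", "continuous", lo=0.0, hi=0.6),
            RangeSpec("tl_learn_ratio", "discrete", options=TL_LEARN_RATIOS),
            RangeSpec("optimizer", "discrete", options=OPTIMIZERS),
            RangeSpec("scaler", "discrete", options=SCALERS),
            RangeSpec("use_da", "flag", options=FLAGS),
            RangeSpec("rotation", "discrete", options=ROTATIONS),
            RangeSpec("width_shift", "continuous", lo=0.0, hi=0.25),
            RangeSpec("height_shift", "continuous", lo=0.0, hi=0.25),
            RangeSpec("shear", "continuous", lo=0.0, hi=0.25),
            RangeSpec("zoom", "continuous", lo=0.0, hi=0.25),
            RangeSpec("horizontal_flip", "flag", options=FLAGS),
            RangeSpec("vertical_flip", "flag", options=FLAGS),
            RangeSpec("brightness", "continuous", lo=0.5, hi=2.0),
        )
    )


# Augmentation sub-cells are inert when the DA flag decodes to "No".
_DA_SUBCELLS = (
    "rotation",
    "width_shift",
    "height_shift",
    "shear",
    "zoom",
    "horizontal_flip",
    "vertical_flip",
    "brightness",
)
_DA_INERT = {
    "rotation": 0,
    "width_shift": 0.0,
    "height_shift": 0.0,
    "shear": 0.0,
    "zoom": 0.0,
    "horizontal_flip": "No",
    "vertical_flip": "No",
    "brightness": (1.0, 1.0),
}


@dataclass(frozen=True)
class TrialConfig:
    """One decoded transfer-learning configuration.

    ``brightness`` is a (lower, upper) multiplier range: the single cell
    decodes to the lower end and the upper end is ``min(2.0, lower + 0.5)``.
    ``unused`` lists the augmentation cells that are inert because the DA
    flag decoded to "No".
    """

    values: dict[str, Any]
    unused: tuple[str, ...] = ()

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    @property
    def use_da(self) -> bool:
        return self.values["use_da"] == "Yes"

    def to_record(self) -> dict[str, Any]:
        """Flat key->value record (brightness flattened to two keys)."""
        rec = {}
        for k, v in self.values.items():
            if k == "brightness":
                rec["brightness_lo"], rec["brightness_hi"] = v
            else:
                rec[k] = v
        rec["unused_cells"] = list(self.unused)
        return rec


@dataclass(frozen=True)
class FeatureMask:
    """Boolean keep/drop flags, one per selectable table attribute."""

    flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.flags) == 0:
            raise ValueError("feature mask cannot have zero length")

    @property
    def n_kept(self) -> int:
        return sum(self.flags)

    def to_string(self) -> str:
        """Serialize as a 0/1 string (the encoded-solution layout)."""
        return "".join("1" if f else "0" for f in self.flags)

    @classmethod
    def from_string(cls, s: str) -> "FeatureMask":
        if set(s) - {"0", "1"}:
            raise ValueError(f"encoded mask must be 0/1 characters, got {s!r}")
        return cls(flags=tuple(c == "1" for c in s))


def map_cell_to_range_index(value: float, n_options: int) -> int:
    """Ceiling range-index decoding: ``ceil(value * n_options)``, 1-based.

    A cell value of 0 is clamped to index 1 so the map is total on [0, 1].
    E.g. value 0.75 over a 12-option list gives index 9.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"cell value {value} outside [0, 1]")
    if n_options < 1:
        raise ValueError(f"need at least one option, got {n_options}")
    index = math.ceil(value * n_options)
    return max(1, min(index, n_options))


def map_cell_to_continuous(value: float, lo: float, hi: float) -> float:
    """Linear decoding of a continuous cell: ``lo + value * (hi - lo)``."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"cell value {value} outside [0, 1]")
    if lo > hi:
        raise ValueError(f"lo {lo} > hi {hi}")
    return lo + value * (hi - lo)


def _decode_cell(value: float, spec: RangeSpec) -> Any:
    if spec.kind in ("discrete", "flag"):
        idx = map_cell_to_range_index(value, len(spec.options))
        return spec.options[idx - 1]
    return map_cell_to_continuous(value, spec.lo, spec.hi)


def map_solution_to_trial_config(
    solution: Sequence[float], space: HyperparameterSpace | None = None
) -> TrialConfig:
    """Decode a 15-cell solution vector into a :class:`TrialConfig`.

    Brightness decodes the cell to the lower multiplier and caps the upper
    at ``lower + 0.5`` (never above 2.0).  When the DA flag decodes to "No"
    the eight augmentation cells take inert values and are marked unused.
    """
    space = space or default_hyperparameter_space()
    solution = np.asarray(solution, dtype=float)
    if solution.shape != (space.dim,):
        raise ValueError(
            f"solution length {solution.shape} does not match the "
            f"{space.dim}-cell space"
        )
    values: dict[str, Any] = {}
    for cell_value, spec in zip(solution, space.cells):
        if spec.name == "brightness":
            lower = map_cell_to_continuous(float(cell_value), spec.lo, spec.hi)
            values[spec.name] = (lower, min(spec.hi, lower + 0.5))
        else:
            values[spec.name] = _decode_cell(float(cell_value), spec)
    unused: tuple[str, ...] = ()
    if values.get("use_da") == "No":
        unused = _DA_SUBCELLS
        for name in _DA_SUBCELLS:
            if name in values:
                values[name] = _DA_INERT[name]
    return TrialConfig(values=values, unused=unused)


def map_solution_to_feature_mask(solution: Sequence[float]) -> FeatureMask:
    """Threshold decoding: keep column i iff cell_i >= 0.5.

    If no cell clears the threshold, the single largest cell is kept
    (ties broken toward the lowest index) so the classifier always sees
    at least one feature.
    """
    solution = np.asarray(solution, dtype=float)
    if solution.ndim != 1 or solution.size == 0:
        raise ValueError("solution must be a non-empty 1-D vector")
    flags = solution >= 0.5
    if not flags.any():
        flags = np.zeros(solution.size, dtype=bool)
        flags[int(np.argmax(solution))] = True
    return FeatureMask(flags=tuple(bool(f) for f in flags))


def extract_data_subset(
    table: pd.DataFrame, mask: FeatureMask, class_column: str = "class"
) -> pd.DataFrame:
    """Restrict a screening table to the kept feature columns plus the label."""
    feature_cols = [c for c in table.columns if c != class_column]
    if len(mask.flags) != len(feature_cols):
        raise ValueError(
            f"mask length {len(mask.flags)} does not match the "
            f"{len(feature_cols)} feature columns"
        )
    kept = [c for c, keep in zip(feature_cols, mask.flags) if keep]
    cols = kept + ([class_column] if class_column in table.columns else [])
    return table[cols].copy()
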