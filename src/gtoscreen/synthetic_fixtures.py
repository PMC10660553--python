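"""Deterministic synthetic fixtures for both dataset kinds.

``generate_screening_table`` emulates an AQ-10-style screening table: ten
binary item scores A1..A10 whose sum is the ``result`` column, demographic
attributes drawn from fixed vocabularies, and a deterministic class rule
``class = YES iff result >= threshold``.  Because the label is a pure
function of the item scores, a tree learner given those columns can reach
100% cross-validated accuracy — which is what makes the table a useful
test bed for wrapper feature selection.

``generate_image_set`` writes a two-class PNG directory tree where class
membership is encoded by the position of a bright square cue (upper-left
vs lower-right quadrant) on a noisy background, so the classes are
separable by construction and a pixel-level probe suffices to classify.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ScreeningGenSpec",
    "ImageGenSpec",
    "SCREENING_COLUMNS",
    "generate_screening_table",
    "generate_image_set",
]

#: The 21-attribute screening schema (20 features + class).
SCREENING_COLUMNS = (
    "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8", "A9", "A10",
    "age", "gender", "ethnicity", "jaundice", "family_pdd",
    "residence", "used_app", "result", "age_desc", "relation",
    "class",
)

_ETHNICITIES = ("Asian", "Black", "Hispanic", "Latino", "Middle Eastern",
                "Others", "Pasifika", "South Asian", "Turkish", "White-European")
_RESIDENCES = ("Argentina", "Brazil", "Egypt", "India", "Jordan",
               "New Zealand", "United Arab Emirates", "United Kingdom",
               "United States", "Viet Nam")
_AGE_DESCS = ("12-15 years", "18 and more", "4-11 years")
_RELATIONS = ("Health care professional", "Parent", "Relative", "Self")
_YES_NO = ("no", "yes")
_GENDERS = ("f", "m")

#: Demographic columns eligible for "?" injection (never the items or class).
_MISSABLE = ("ethnicity", "relation", "residence", "age_desc")


@dataclass(frozen=True)
class ScreeningGenSpec:
    """Conditions for one generated screening table.

    ``item_prob`` is the Bernoulli rate of each A-item; ``threshold`` is the
    class cut on the item sum (YES iff result >= threshold, default 7, the
    AQ-10 screening cut); ``missing_rate`` injects "?" markers into
    demographic cells; ``n_noise_demographics`` appends that many extra pure-
    noise categorical columns beyond the fixed 21-attribute schema.
    """

    n: int = 1100
    item_prob: float = 0.5
    threshold: int = 7
    n_noise_demographics: int = 0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.item_prob <= 1.0:
            raise ValueError(f"item_prob must be in [0, 1], got {self.item_prob}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.n_noise_demographics < 0:
            raise ValueError("n_noise_demographics must be >= 0")


def generate_screening_table(spec: ScreeningGenSpec) -> pd.DataFrame:
    """Generate a screening table under the deterministic label rule.

    The invariant ``result == A1 + ... + A10`` and
    ``class == YES iff result >= threshold`` holds for every row, so the
    label is recomputable from the item columns alone.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    items = (rng.random((n, 10)) < spec.item_prob).astype(int)
    result = items.sum(axis=1)
    cls = np.where(result >= spec.threshold, "YES", "NO")

    table = pd.DataFrame(items, columns=[f"A{i}" for i in range(1, 11)])
    table["age"] = rng.integers(4, 60, size=n)
    table["gender"] = rng.choice(_GENDERS, size=n)
    table["ethnicity"] = rng.choice(_ETHNICITIES, size=n)
    table["jaundice"] = rng.choice(_YES_NO, size=n)
    table["family_pdd"] = rng.choice(_YES_NO, size=n)
    table["residence"] = rng.choice(_RESIDENCES, size=n)
    table["used_app"] = rng.choice(_YES_NO, size=n)
    table["result"] = result
    table["age_desc"] = rng.choice(_AGE_DESCS, size=n)
    table["relation"] = rng.choice(_RELATIONS, size=n)
    table["class"] = cls

    if spec.missing_rate > 0:
        for col in _MISSABLE:
            hit = rng.random(n) < spec.missing_rate
            table.loc[hit, col] = "?"

    for j in range(spec.n_noise_demographics):
        table.insert(
            len(table.columns) - 1,
            f"noise_{j + 1}",
            rng.choice(("a", "b", "c", "d"), size=n),
        )
    return table


@dataclass(frozen=True)
class ImageGenSpec:
    """Conditions for one generated two-class image tree.

    ``cue`` selects the class-separating signal: ``blob`` places a bright
    square in the upper-left (class 0) or lower-right (class 1) quadrant;
    ``ellipse`` varies the aspect ratio of a centered bright ellipse.
    ``noise`` is the standard deviation of additive Gaussian pixel noise
    on the [0, 1] intensity scale.
    """

    n_per_class: int = 50
    size: int = 128
    cue: str = "blob"
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError(f"size must be >= 32, got {self.size}")
        if self.cue not in ("blob", "ellipse"):
            raise ValueError(f"cue must be 'blob' or 'ellipse', got {self.cue!r}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _render_image(label: int, spec: ImageGenSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.size
    img = np.full((s, s, 3), 0.2)
    q = s // 4
    if spec.cue == "blob":
        r0, c0 = (q, q) if label == 0 else (3 * q, 3 * q)
        half = max(2, s // 16)
        img[r0 - half:r0 + half, c0 - half:c0 + half, :] = 0.95
    else:
        rr, cc = np.mgrid[0:s, 0:s]
        a, b = (s / 3.0, s / 8.0) if label == 0 else (s / 8.0, s / 3.0)
        inside = ((rr - s / 2) / a) ** 2 + ((cc - s / 2) / b) ** 2 <= 1.0
        img[inside] = 0.95
    if spec.noise > 0:
        img = img + rng.normal(0.0, spec.noise, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_image_set(spec: ImageGenSpec, out_dir) -> Path:
    """Write the two-class PNG tree (``class_0/``, ``class_1/``) and a
    sidecar JSON echoing the generation spec; returns the root path."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    for label in (0, 1):
        sub = root / f"class_{label}"
        sub.mkdir(exist_ok=True)
        for i in range(spec.n_per_class):
            img = _render_image(label, spec, rng)
            arr = (img * 255).round().astype(np.uint8)
            Image.fromarray(arr).save(sub / f"img_{i:04d}.png")
    (root / "genspec.json").write_text(json.dumps(asdict(spec), indent=2))
    return root
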