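"""Desk-scale synthetic stand-ins for the three study datasets.

Two generators:

- :func:`make_image_set` — two-class grayscale "medical-style" images: a
  smoothed, exactly zero-mean Gaussian texture on a 0.5 background, with the
  positive class carrying 1-3 bright elliptical blobs.  Because the texture
  is mean-centred per image, at zero pixel noise every negative image has
  pixel mean exactly 0.5 and every positive image strictly more, so the
  classes are separable by construction.
- :func:`make_cholesterol_set` — a cholesterol panel whose ground truth is
  the clinical Friedewald relation LDL-C = TC - HDL-C - TG/5 (mg/dL) plus
  Gaussian noise; age, sex, height and weight are nuisance covariates with
  no effect on the target.

Both are bitwise deterministic per seed.  Fixtures round-trip through ``.npz``
archives (images) and CSV (tabular).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticImageSet",
    "SyntheticCholesterolSet",
    "make_image_set",
    "make_cholesterol_set",
    "save_fixture",
    "load_fixture",
    "FixtureError",
    "CHOLESTEROL_COLUMNS",
]

CHOLESTEROL_COLUMNS = ["age", "sex", "height", "weight", "TC", "HDL_C", "TG", "LDL_C"]

#: peak amplitude of the background texture (keeps negatives inside [0.25, 0.75])
_TEXTURE_AMPLITUDE = 0.25


class FixtureError(IOError):
    """A fixture file is missing or unreadable."""


@dataclass
class SyntheticImageSet:
    images: np.ndarray  # [n, H, W, 1] float64 in [0, 1]
    labels: np.ndarray  # [n] int, 1 = lesion present
    params: dict
    seed: int

    def __post_init__(self) -> None:
        if self.images.min() < 0 or self.images.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")


@dataclass
class SyntheticCholesterolSet:
    table: pd.DataFrame
    params: dict
    seed: int

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != CHOLESTEROL_COLUMNS:
            raise ValueError(f"columns must be exactly {CHOLESTEROL_COLUMNS}, got {list(t.columns)}")
        if not ((t["TC"] > t["HDL_C"]).all() and (t["HDL_C"] > 0).all()):
            raise ValueError("invariant TC > HDL_C > 0 violated")
        if not ((t["TG"] > 0).all() and (t["LDL_C"] >= 0).all()):
            raise ValueError("invariant TG > 0, LDL_C >= 0 violated")


def make_image_set(
    n: int,
    size: int,
    lesion_contrast: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticImageSet:
    """Generate ``n`` grayscale ``size`` x ``size`` images.

    Classes are balanced to within one sample and label order is shuffled
    deterministically.  ``lesion_contrast`` must be positive: it is the peak
    brightness each elliptical blob adds, and the sole class difference.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if size < 8:
        raise ValueError("need size >= 8")
    if lesion_contrast <= 0:
        raise ValueError("lesion_contrast must be > 0; classes would be indistinguishable")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0x1347E,)))
    n_pos = n // 2
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(n)]

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    images = np.empty((n, size, size, 1))
    for i in range(n):
        texture = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 16.0)
        texture -= texture.mean()
        peak = np.abs(texture).max()
        if peak > 0:
            texture *= _TEXTURE_AMPLITUDE / peak
        img = 0.5 + texture
        if labels[i] == 1:
            for _ in range(rng.integers(1, 4)):
                rx = rng.uniform(size / 10.0, size / 5.0)
                ry = rng.uniform(size / 10.0, size / 5.0)
                cx = rng.uniform(rx, size - rx)
                cy = rng.uniform(ry, size - ry)
                img = img + lesion_contrast * np.exp(
                    -3.0 * (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
                )
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, (size, size))
        images[i, :, :, 0] = np.clip(img, 0.0, 1.0)

    params = {
        "n": n,
        "size": size,
        "lesion_contrast": lesion_contrast,
        "noise_sd": noise_sd,
    }
    return SyntheticImageSet(images, labels, params, seed)


def make_cholesterol_set(n: int, noise_sd: float = 5.0, seed: int = 0) -> SyntheticCholesterolSet:
    """Generate an ``n``-row cholesterol panel with Friedewald ground truth.

    Covariates: age ~ U(20, 80); sex ~ Bernoulli(0.5); height ~ N(165, 10);
    weight ~ N(70, 15); TC ~ N(190, 35) truncated below at 60 mg/dL;
    TG ~ LogNormal(ln 120, 0.4) truncated above at 5(TC - 6); HDL-C ~
    N(55, 12) truncated to (0, TC - TG/5 - 1).  The truncations guarantee a
    strictly positive noise-free Friedewald value, so the identity holds
    exactly at zero noise.  Target: LDL-C = TC - HDL-C - TG/5 +
    N(0, noise_sd), floored at 0.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xC401,)))
    age = rng.uniform(20.0, 80.0, n)
    sex = rng.integers(0, 2, n)
    height = rng.normal(165.0, 10.0, n)
    weight = rng.normal(70.0, 15.0, n)
    tc = stats.truncnorm.rvs(
        (60.0 - 190.0) / 35.0, np.inf, loc=190.0, scale=35.0, size=n, random_state=rng
    )
    # TG truncated above so the Friedewald value stays positive: TG < 5(TC - 6)
    mu_tg, sd_tg = np.log(120.0), 0.4
    cap = stats.norm.cdf((np.log(5.0 * (tc - 6.0)) - mu_tg) / sd_tg)
    tg = np.exp(mu_tg + sd_tg * stats.norm.ppf(rng.uniform(0.0, cap, n)))
    hdl = stats.truncnorm.rvs(
        (0.0 - 55.0) / 12.0,
        (tc - tg / 5.0 - 1.0 - 55.0) / 12.0,
        loc=55.0,
        scale=12.0,
        size=n,
        random_state=rng,
    )
    ldl = tc - hdl - tg / 5.0
    if noise_sd > 0:
        ldl = ldl + rng.normal(0.0, noise_sd, n)
    ldl = np.maximum(ldl, 0.0)
    table = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "height": height,
            "weight": weight,
            "TC": tc,
            "HDL_C": hdl,
            "TG": tg,
            "LDL_C": ldl,
        }
    )
    return SyntheticCholesterolSet(table, {"n": n, "noise_sd": noise_sd}, seed)


# ---------------------------------------------------------------------------
# fixture round trip


def save_fixture(dataset, path) -> Path:
    """Write an image set as ``.npz`` or a cholesterol set as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(dataset, SyntheticImageSet):
        np.savez(
            path,
            images=dataset.images,
            labels=dataset.labels,
            meta=np.frombuffer(
                json.dumps({"params": dataset.params, "seed": dataset.seed}).encode(), dtype=np.uint8
            ),
        )
    elif isinstance(dataset, SyntheticCholesterolSet):
        dataset.table.to_csv(path, index=False, float_format="%.6f")
    else:
        raise TypeError(f"cannot save {type(dataset).__name__}")
    return path


def load_fixture(path, kind: str):
    """Load a fixture written by :func:`save_fixture`.

    ``kind`` is ``"images"`` or ``"cholesterol"``.  Missing files raise
    :class:`FixtureError` with a missing-file message; unreadable or
    malformed files raise :class:`FixtureError` marked corrupt.
    """
    path = Path(path)
    if not path.exists():
        raise FixtureError(f"fixture file not found: {path}")
    if kind == "images":
        try:
            with np.load(path) as z:
                meta = json.loads(bytes(z["meta"]).decode())
                return SyntheticImageSet(z["images"], z["labels"], meta["params"], meta["seed"])
        except FixtureError:
            raise
        except Exception as exc:
            raise FixtureError(f"corrupt image fixture {path}: {exc}") from exc
    if kind == "cholesterol":
        try:
            table = pd.read_csv(path)
        except Exception as exc:
            raise FixtureError(f"corrupt cholesterol fixture {path}: {exc}") from exc
        if list(table.columns) != CHOLESTEROL_COLUMNS:
            raise FixtureError(
                f"corrupt cholesterol fixture {path}: header {list(table.columns)}"
            )
        return SyntheticCholesterolSet(table, {"n": len(table)}, seed=-1)
    raise ValueError(f"unknown fixture kind {kind!r}")
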