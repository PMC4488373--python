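"""Optical-imagery indices: DOS1 offset correction and the Tasseled Cap.

Works on 6-band reflectance stacks (Landsat-TM-like bands 1-5 and 7,
values in [0, 1]). Dark-object subtraction (DOS1) removes a per-band
additive haze offset estimated from the darkest pixels; the Tasseled
Cap transform projects the six bands onto fixed brightness, greenness
and wetness axes. Coefficients ship in a versioned YAML config so other
sensor generations can be swapped in.

Radiometric calibration from raw digital numbers is out of scope: the
input is assumed to already be top-of-atmosphere reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml


@dataclass
class ReflectanceStack:
    """Six co-registered reflectance bands plus a season tag."""

    bands: np.ndarray  # shape (6, nrows, ncols), values in [0, 1]
    season: str = ""

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3 or self.bands.shape[0] != 6:
            raise ValueError("expected a (6, nrows, ncols) band stack")


@dataclass
class TasseledCapStack:
    brightness: np.ndarray
    greenness: np.ndarray
    wetness: np.ndarray
    season: str = ""


def load_tasseled_cap_coefficients(path: str | None = None) -> np.ndarray:
    """3x6 coefficient matrix (brightness, greenness, wetness rows)."""
    if path is None:
        text = resources.files("streamsdm.data").joinpath("tasseled_cap_tm.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    coeff = np.array([cfg["brightness"], cfg["greenness"], cfg["wetness"]], dtype=float)
    if coeff.shape != (3, 6):
        raise ValueError("coefficient file must define three 6-element vectors")
    return coeff


def dark_object_value(band: np.ndarray, dark_quantile: float) -> float:
    """Dark-object reflectance: the smallest value v with at least
    ceil(q*n) band values <= v (an order statistic, ties included)."""
    flat = np.sort(np.asarray(band, dtype=float).ravel())
    if flat.size == 0:
        raise ValueError("empty band")
    k = max(int(np.ceil(dark_quantile * flat.size)), 1)
    return float(flat[k - 1])


def dos1_correct(stack: ReflectanceStack, dark_quantile: float = 0.01) -> ReflectanceStack:
    """Subtract each band's dark-object value and clip at zero.

    A small quantile (default 1%) rather than the absolute minimum is
    used so single-pixel artifacts cannot set the offset.
    """
    if not 0.0 <= dark_quantile <= 0.05:
        raise ValueError("dark_quantile must be in [0, 0.05]")
    corrected = np.empty_like(stack.bands)
    for b in range(6):
        q = dark_object_value(stack.bands[b], dark_quantile)
        corrected[b] = np.clip(stack.bands[b] - q, 0.0, None)
    return ReflectanceStack(corrected, stack.season)


def tasseled_cap(stack: ReflectanceStack, coefficients: np.ndarray | None = None) -> TasseledCapStack:
    """Brightness/greenness/wetness as fixed linear combinations of the bands."""
    coeff = load_tasseled_cap_coefficients() if coefficients is None else np.asarray(coefficients, dtype=float)
    if coeff.shape != (3, 6):
        raise ValueError("coefficient matrix must be 3x6")
    if stack.bands.shape[0] != coeff.shape[1]:
        raise ValueError("band count mismatch")
    idx = np.tensordot(coeff, stack.bands, axes=(1, 0))
    return TasseledCapStack(idx[0], idx[1], idx[2], stack.season)
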