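"""Hyperspectral reflectance handling: dark/white calibration, ROI spectral
extraction, working-range trimming, and the three spectral pretreatments
(moving-window smoothing, first-derivative Savitzky-Golay, standard normal
variate).

The instrument convention modelled here is a Vis/NIR line-scan camera
recording 568 bands over 400-950 nm.  Wavelengths follow a uniform grid with
a half-open upper endpoint, ``lambda_i = 400 + i * 550/568``; under this
convention trimming to the 450-900 nm working range retains exactly 465
bands.  (An endpoint-inclusive grid would retain 464; the half-open
convention is therefore load-bearing and deliberate.)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpectralGrid",
    "Hypercube",
    "CalibrationPair",
    "ReflectanceSpectrum",
    "CalibrationError",
    "SamplingError",
    "PreprocessingError",
    "calibrate_hypercube",
    "trim_bands",
    "trim_spectra_table",
    "extract_roi_spectrum",
    "preprocess_spectra",
    "MovingWindowSmoother",
    "SavitzkyGolayDerivative",
    "StandardNormalVariate",
    "write_envi",
    "read_envi",
]


class CalibrationError(ValueError):
    """Raised when white and dark references coincide somewhere."""


class SamplingError(ValueError):
    """Raised when ROI blocks cannot be placed inside the fruit mask."""


class PreprocessingError(ValueError):
    """Raised for degenerate spectra (e.g. SNV of a constant row)."""


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength axis in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("grid needs at least two wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def default(cls, n_bands: int = 568, lo: float = 400.0, hi: float = 950.0) -> "SpectralGrid":
        # half-open upper endpoint: lambda_i = lo + i * (hi - lo) / n_bands
        step = (hi - lo) / n_bands
        return cls(lo + np.arange(n_bands) * step)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def trim_mask(self, lo: float, hi: float) -> np.ndarray:
        if lo > hi:
            raise ValueError(f"invalid trim range: lo={lo} > hi={hi}")
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise ValueError(f"trim range [{lo}, {hi}] does not overlap the grid")
        return mask

    def trimmed(self, lo: float, hi: float) -> "SpectralGrid":
        return SpectralGrid(self.wavelengths[self.trim_mask(lo, hi)])


@dataclass
class Hypercube:
    """rows x cols x bands image stack with its wavelength grid."""

    data: np.ndarray
    grid: SpectralGrid
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be rows x cols x bands")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"band axis ({self.data.shape[2]}) does not match grid ({self.grid.n_bands})"
            )


@dataclass
class CalibrationPair:
    """Dark and white reference images sharing the target's shape/grid."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white references must share a shape")


@dataclass
class ReflectanceSpectrum:
    """ROI-averaged reflectance of one fruit on a (possibly trimmed) grid."""

    values: np.ndarray
    grid: SpectralGrid
    fruit_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError("spectrum length must match the grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")


def calibrate_hypercube(raw: Hypercube, refs: CalibrationPair) -> Hypercube:
    """Reflectance calibration ``(raw - dark) / (white - dark)`` per pixel/band."""
    if refs.dark.shape != raw.data.shape:
        raise ValueError("reference shape does not match the raw cube")
    denom = refs.white - refs.dark
    bad = np.argwhere(denom == 0)
    if bad.size:
        coords = ", ".join(str(tuple(int(v) for v in c)) for c in bad[:5])
        raise CalibrationError(
            f"white and dark references coincide at {bad.shape[0]} locations "
            f"(first: {coords})"
        )
    return Hypercube((raw.data - refs.dark) / denom, raw.grid, calibrated=True)


def trim_bands(obj: Hypercube | ReflectanceSpectrum, lo: float = 450.0, hi: float = 900.0):
    """Restrict a cube or spectrum to wavelengths with ``lo <= lambda <= hi``."""
    mask = obj.grid.trim_mask(lo, hi)
    grid = SpectralGrid(obj.grid.wavelengths[mask])
    if isinstance(obj, Hypercube):
        return Hypercube(obj.data[:, :, mask], grid, obj.calibrated)
    return replace(obj, values=obj.values[mask], grid=grid)


def trim_spectra_table(table: pd.DataFrame, lo: float = 450.0, hi: float = 900.0) -> pd.DataFrame:
    """Trim a fruits x wavelengths table whose columns are wavelengths (nm)."""
    if lo > hi:
        raise ValueError(f"invalid trim range: lo={lo} > hi={hi}")
    wl = table.columns.astype(float)
    keep = (wl >= lo) & (wl <= hi)
    if not keep.any():
        raise ValueError(f"trim range [{lo}, {hi}] does not overlap the table columns")
    return table.loc[:, keep]


def _block_placements(mask: np.ndarray, block: int) -> np.ndarray:
    """Top-left corners (i, j) of fully-inside-mask block placements."""
    mask = np.asarray(mask, dtype=bool)
    r, c = mask.shape
    if r < block or c < block:
        return np.empty((0, 2), dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(mask, (block, block))
    ok = windows.all(axis=(2, 3))
    return np.argwhere(ok)


def extract_roi_spectrum(
    cube: Hypercube,
    mask: np.ndarray,
    n_blocks: int = 4,
    block_size: int = 5,
    seed: int | None = None,
    fruit_id: str | None = None,
) -> ReflectanceSpectrum:
    """Average reflectance over ``n_blocks`` random non-overlapping
    ``block_size x block_size`` pixel blocks placed inside the fruit mask.

    Block sampling is seeded; the same cube, mask and seed give identical
    block placement and hence an identical spectrum.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match the cube's spatial axes")
    placements = _block_placements(mask, block_size)
    if placements.shape[0] < n_blocks:
        raise SamplingError(
            f"mask admits only {placements.shape[0]} candidate {block_size}x{block_size} "
            f"placements; {n_blocks} required"
        )
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int]] = []
    for _ in range(200):        # greedy placement with seeded restarts
        order = rng.permutation(placements.shape[0])
        chosen = []
        for k in order:
            i, j = placements[k]
            if all(abs(i - ci) >= block_size or abs(j - cj) >= block_size
                   for ci, cj in chosen):
                chosen.append((int(i), int(j)))
                if len(chosen) == n_blocks:
                    break
        if len(chosen) == n_blocks:
            break
    if len(chosen) < n_blocks:
        raise SamplingError(
            f"could not place {n_blocks} non-overlapping blocks inside the mask"
        )
    pixels = np.concatenate(
        [cube.data[i : i + block_size, j : j + block_size, :].reshape(-1, cube.grid.n_bands)
         for i, j in chosen]
    )
    return ReflectanceSpectrum(pixels.mean(axis=0), cube.grid, fruit_id=fruit_id)


# ---------------------------------------------------------------------------
# pretreatments

class MovingWindowSmoother(TransformerMixin, BaseEstimator):
    """Centered moving-average smoothing with a shrinking window at the edges.

    The window shrinks one-sidedly near the spectrum ends so the output keeps
    the input length and a constant spectrum maps to itself exactly.
    """

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] < self.window:
            raise PreprocessingError(
                f"need at least {self.window} bands, got {X.shape[1]}"
            )
        half = self.window // 2
        p = X.shape[1]
        csum = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
        idx = np.arange(p)
        lo = np.maximum(0, idx - half)
        hi = np.minimum(p, idx + half + 1)
        out = (csum[:, hi] - csum[:, lo]) / (hi - lo)
        return out[0] if one_d else out


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """First-order Savitzky-Golay derivative (window 5, quadratic fit).

    The derivative is reported per band index (unit sample spacing); edges use
    a one-sided polynomial fit to the terminal window.
    """

    def __init__(self, window: int = 5, polyorder: int = 2):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] < self.window:
            raise PreprocessingError(
                f"need at least {self.window} bands, got {X.shape[1]}"
            )
        out = savgol_filter(
            X, window_length=self.window, polyorder=self.polyorder,
            deriv=1, axis=1, mode="interp",
        )
        return out[0] if one_d else out


class StandardNormalVariate(TransformerMixin, BaseEstimator):
    """Per-spectrum centering and scaling to unit sample SD (divisor n-1)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        ids = list(X.index) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        X = np.atleast_2d(X)
        sd = X.std(axis=1, ddof=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = [str(ids[i]) if ids is not None else f"row {i}" for i in flat]
            raise PreprocessingError(
                f"SNV undefined for constant spectra: {', '.join(names[:5])}"
            )
        out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        return out[0] if one_d else out


_METHODS = {
    "MWS": MovingWindowSmoother,
    "SG1D": SavitzkyGolayDerivative,
    "SNV": StandardNormalVariate,
}


def preprocess_spectra(spectra, method: str):
    """Apply one pretreatment ("MWS", "SG1D" or "SNV") to a fruits x bands
    matrix.  DataFrames keep their index and columns."""
    if method not in _METHODS:
        raise ValueError(f"unknown pretreatment {method!r}; choose from {sorted(_METHODS)}")
    transformer = _METHODS[method]()
    out = transformer.fit_transform(spectra)
    if isinstance(spectra, pd.DataFrame):
        return pd.DataFrame(out, index=spectra.index, columns=spectra.columns)
    return out


# ---------------------------------------------------------------------------
# minimal ENVI I/O (band-sequential float32 + text header)

def write_envi(path_stem: str | Path, cube: Hypercube) -> tuple[Path, Path]:
    """Write a cube as ENVI band-sequential float32 (.img) plus text header (.hdr)."""
    stem = Path(path_stem)
    hdr, img = stem.with_suffix(".hdr"), stem.with_suffix(".img")
    rows, cols, bands = cube.data.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.wavelengths)
    hdr.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    np.ascontiguousarray(np.moveaxis(cube.data, 2, 0), dtype="<f4").tofile(img)
    return hdr, img


def read_envi(hdr_path: str | Path) -> Hypercube:
    """Read a band-sequential float32 ENVI cube written by :func:`write_envi`."""
    hdr_path = Path(hdr_path)
    text = hdr_path.read_text()
    def _int(key: str) -> int:
        m = re.search(rf"^{key}\s*=\s*(\d+)", text, re.M)
        if not m:
            raise ValueError(f"missing ENVI header field {key!r}")
        return int(m.group(1))
    cols, rows, bands = _int("samples"), _int("lines"), _int("bands")
    if _int("data type") != 4:
        raise ValueError("only float32 (data type 4) supported")
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", text, re.S)
    if not m:
        raise ValueError("missing wavelength block in ENVI header")
    wl = np.array([float(v) for v in m.group(1).replace("\n", " ").split(",") if v.strip()])
    data = np.fromfile(hdr_path.with_suffix(".img"), dtype="<f4")
    data = data.reshape(bands, rows, cols)
    return Hypercube(np.moveaxis(data, 0, 2).astype(float), SpectralGrid(wl))
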