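"""File I/O, micrograph stripe extraction, and 1D noise whitening.

Measurements and templates are plain single-column text/CSV (``#`` comments
allowed). Detections, ground truth and gap curves travel as JSON with the
coordinate convention ("0-based left edge") declared in the schema.

Whitening is the standard preprocessing step for measurements with colored
(non-flat-spectrum) noise: the noise power spectral density is estimated
from a signal-free region with an averaged modified periodogram, and the
measurement's Fourier coefficients are divided by the square root of that
density, so the output noise is approximately white with unit variance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .types import Detection, InfeasibleInputError, Measurement, Template, as_measurement

logger = logging.getLogger("sigdp")

__all__ = [
    "NoiseRegion",
    "whiten",
    "extract_stripe",
    "read_vector",
    "write_vector",
    "read_measurement",
    "read_template",
    "write_detection",
    "read_detection",
    "write_truth",
    "read_truth",
    "read_micrograph",
]

SPECTRUM_FLOOR_REL = 1e-6
SEGMENT_LENGTH = 256


@dataclass(frozen=True)
class NoiseRegion:
    """A signal-free interval [start, end) of a measurement, used to estimate
    the noise power spectrum. Must be long enough for a stable estimate."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InfeasibleInputError("need 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def _noise_psd_twosided(noise: np.ndarray, nperseg: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided PSD estimate on [0, 0.5] via Welch with half-overlapping
    segments. Returned so that white noise of variance v has PSD ~= v."""
    freqs, psd = _sig.welch(
        noise,
        fs=1.0,
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        return_onesided=True,
        scaling="density",
    )
    # undo the one-sided doubling (DC, and Nyquist for even nperseg, are not doubled)
    psd = psd.copy()
    if nperseg % 2 == 0:
        psd[1:-1] /= 2.0
    else:
        psd[1:] /= 2.0
    return freqs, psd


def whiten(y, region: NoiseRegion, *, min_region: int | None = None, power: bool = False) -> Measurement:
    """Whiten a measurement using a noise-only region.

    The noise PSD is estimated from ``y[region.start:region.end]`` with an
    averaged modified periodogram (half-overlapping segments of length
    min(256, region length)), interpolated onto the measurement's rFFT grid,
    floored at ``1e-6 * max``, and the measurement's spectrum is divided by
    its square root (amplitude normalization: output noise is approximately
    unit-variance white). With ``power=True`` the spectrum is divided by the
    PSD itself (the literal inverse-power reading).

    Raises
    ------
    InfeasibleInputError
        If the region is out of range, shorter than ``min_region``
        (default 8 samples), or has zero power.
    """
    y = as_measurement(y)
    n = y.length
    if region.end > n:
        raise InfeasibleInputError("noise region extends past the measurement")
    if min_region is None:
        min_region = 8
    if region.length < min_region:
        raise InfeasibleInputError(
            f"noise region of {region.length} samples is too short (< {min_region})"
        )
    noise = y.samples[region.start : region.end]
    if not np.any(noise != 0):
        raise InfeasibleInputError("noise region is identically zero")

    nperseg = min(SEGMENT_LENGTH, region.length)
    freqs, psd = _noise_psd_twosided(noise, nperseg)

    floor = SPECTRUM_FLOOR_REL * float(psd.max())
    n_floored = int(np.sum(psd < floor))
    if n_floored:
        logger.warning("whiten: %d spectrum bins floored at %.3g", n_floored, floor)
    psd = np.maximum(psd, floor)

    grid = np.fft.rfftfreq(n, d=1.0)
    psd_interp = np.interp(grid, freqs, psd)
    spectrum = np.fft.rfft(y.samples)
    denom = psd_interp if power else np.sqrt(psd_interp)
    out = np.fft.irfft(spectrum / denom, n=n)
    return Measurement(samples=out, noise_variance=None if power else 1.0)


def extract_stripe(micrograph: np.ndarray, axis: str, index: int) -> Measurement:
    """Extract one row or column of a 2D image as a 1D measurement."""
    img = np.asarray(micrograph, dtype=float)
    if img.ndim != 2:
        raise InfeasibleInputError("micrograph must be a 2D array")
    if axis not in ("row", "column"):
        raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")
    n_rows, n_cols = img.shape
    limit = n_rows if axis == "row" else n_cols
    if not (0 <= index < limit):
        raise IndexError(f"{axis} index {index} out of range [0, {limit})")
    stripe = img[index, :] if axis == "row" else img[:, index]
    return Measurement(samples=stripe.copy())


def read_micrograph(path: str | Path) -> np.ndarray:
    """Read a 2D micrograph: MRC when the optional ``mrcfile`` reader is
    installed, else whitespace-delimited text."""
    path = Path(path)
    if path.suffix.lower() in (".mrc", ".mrcs", ".map"):
        try:
            import mrcfile  # optional dependency
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError(
                "reading MRC files requires the optional 'mrcfile' package"
            ) from exc
        with mrcfile.open(path, permissive=True) as f:  # pragma: no cover
            return np.asarray(f.data, dtype=float)
    return np.loadtxt(path, dtype=float)


# ---------------------------------------------------------------------------
# plain-text vectors and JSON artifacts


def read_vector(path: str | Path) -> np.ndarray:
    """Read a single-column plain-text/CSV vector; '#' starts a comment."""
    v = np.loadtxt(path, comments="#", dtype=float)
    return np.atleast_1d(v)


def write_vector(path: str | Path, values: np.ndarray, header: str = "") -> None:
    np.savetxt(path, np.asarray(values, dtype=float), header=header)


def read_measurement(path: str | Path) -> Measurement:
    return Measurement(samples=read_vector(path))


def read_template(path: str | Path) -> Template:
    return Template(values=read_vector(path))


def write_detection(path: str | Path, det: Detection) -> None:
    Path(path).write_text(json.dumps(det.to_dict(), indent=2) + "\n")


def read_detection(path: str | Path) -> Detection:
    d = json.loads(Path(path).read_text())
    return Detection(
        locations=tuple(d["locations"]),
        objective=float(d["objective"]),
        k=int(d["k"]),
        objective_curve=(
            np.asarray(d["objective_curve"]) if "objective_curve" in d else None
        ),
        complete=bool(d.get("complete", True)),
    )


def write_truth(path: str | Path, locations, l: int, sigma2: float | None = None) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "locations": [int(v) for v in locations],
                "template_length": int(l),
                "noise_variance": sigma2,
                "coordinate_convention": "0-based left edge",
            },
            indent=2,
        )
        + "\n"
    )


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
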