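"""Optical (PSF) and detector (analog shot-noise) models.

The illumination profile of a confocal laser scanning microscope is modelled
as a 2D Gaussian ``g(r) = exp(-2 r^2 / w0^2)`` with e^-2 radius ``w0``.
Densities are expressed in entities per *beam area* ``BA = integral g dA =
pi w0^2 / 2``, the convention under which the image mean intensity is exactly
``sum_i N_i eps_i`` for populations of ``N_i`` entities per BA with quantal
brightness ``eps_i``.

An analog PMT adds intensity-dependent noise: the variance of the measured
signal grows linearly with the mean, ``var(I) = intercept + slope * I``, over
a finite linear range. The slope and intercept are calibrated from a
uniform-illumination control recording (mirror in the focal plane) and reused
by every downstream correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .errors import DegenerateFitError, InvalidDataError

__all__ = [
    "PsfModel",
    "DetectorModel",
    "shape_factor",
    "shape_factor_quadrature",
    "fit_detector_noise",
    "variance_trace_from_pointscan",
]


@dataclass(frozen=True)
class PsfModel:
    """Gaussian illumination profile.

    Parameters
    ----------
    e2_radius : float
        Radius (µm) at which the profile falls to e^-2 of its peak (w0).
    pixel_size : float
        Image pixel size (µm). Must oversample the PSF (pixel_size < w0).
    """

    e2_radius: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.e2_radius <= 0:
            raise ValueError("e2_radius must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixel_size >= self.e2_radius:
            raise ValueError(
                "pixel_size must be smaller than e2_radius (oversampled PSF)"
            )

    @property
    def beam_area(self) -> float:
        """Integral of the peak-normalized profile over the plane (µm²)."""
        return np.pi * self.e2_radius**2 / 2.0

    @property
    def beam_area_pixels(self) -> float:
        """Beam area expressed in pixels."""
        return self.beam_area / self.pixel_size**2

    def profile(self, r: np.ndarray | float) -> np.ndarray | float:
        """Peak-normalized intensity at radial distance ``r`` (µm)."""
        return np.exp(-2.0 * np.asarray(r, dtype=float) ** 2 / self.e2_radius**2)

    def shape_factor(self, n: int) -> float:
        return shape_factor(self, n)


def shape_factor(psf: PsfModel, n: int) -> float:
    """Moment shape factor gamma_n = int g^n dA / int g dA.

    For the 2D Gaussian profile the analytic value is 1/n: raising the
    profile to the n-th power shrinks its e^-2 radius by sqrt(n), so the
    integral shrinks n-fold.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"moment order n must be a positive integer, got {n!r}")
    return 1.0 / int(n)


def shape_factor_quadrature(psf: PsfModel, n: int, rmax_factor: float = 12.0) -> float:
    """gamma_n by direct radial quadrature of the profile; oracle for shape_factor."""
    if int(n) != n or n < 1:
        raise ValueError(f"moment order n must be a positive integer, got {n!r}")
    w0 = psf.e2_radius
    rmax = rmax_factor * w0

    def integrand(r: float, power: int) -> float:
        return np.exp(-2.0 * power * r**2 / w0**2) * 2.0 * np.pi * r

    num, _ = integrate.quad(integrand, 0.0, rmax, args=(int(n),))
    den, _ = integrate.quad(integrand, 0.0, rmax, args=(1,))
    return num / den


@dataclass(frozen=True)
class DetectorModel:
    """Linear variance-vs-mean law of an analog PMT.

    ``variance(I) = intercept + slope * I`` for mean intensities in
    ``[0, linear_max]``; above ``saturation`` the detector clips.
    """

    slope: float
    intercept: float = 0.0
    linear_max: float = np.inf
    saturation: float = np.inf
    stderr_slope: float = field(default=0.0, compare=False)
    stderr_intercept: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be non-negative")
        if self.intercept < 0:
            raise ValueError("intercept must be non-negative")
        if np.isinf(self.linear_max) and np.isfinite(self.saturation):
            object.__setattr__(self, "linear_max", float(self.saturation))
        if not (0 < self.linear_max <= self.saturation):
            raise ValueError("need 0 < linear_max <= saturation")

    def variance(self, mean: np.ndarray | float) -> np.ndarray | float:
        """Predicted measurement variance at mean intensity ``mean``."""
        return self.intercept + self.slope * np.asarray(mean, dtype=float)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "linear_max": self.linear_max if np.isfinite(self.linear_max) else None,
                    "saturation": self.saturation if np.isfinite(self.saturation) else None,
                    "stderr_slope": self.stderr_slope,
                    "stderr_intercept": self.stderr_intercept,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "DetectorModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            slope=d["slope"],
            intercept=d.get("intercept", 0.0),
            linear_max=d.get("linear_max") or np.inf,
            saturation=d.get("saturation") or np.inf,
            stderr_slope=d.get("stderr_slope", 0.0),
            stderr_intercept=d.get("stderr_intercept", 0.0),
        )


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares line with standard errors; tolerates an exact fit."""
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    s2 = np.sum(resid**2) / dof
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return slope, intercept, se_slope, se_intercept, resid


def fit_detector_noise(
    pairs: Sequence[tuple[float, float]],
    saturation: float = np.inf,
    min_points: int = 3,
    r2_min: float = 0.99,
    outlier_sigma: float = 3.0,
) -> DetectorModel:
    """Fit the linear variance-vs-mean law to uniform-illumination statistics.

    Real analog detectors leave the linear regime at high signal, so only the
    initial (low-mean) part of the curve is fitted: starting from the
    ``min_points`` lowest means, the fitted range is extended point by point
    while the fit stays good (R² >= ``r2_min``) and the candidate point sits
    within ``outlier_sigma`` residual standard deviations of the current line.
    ``linear_max`` records where extension stopped.

    Parameters
    ----------
    pairs
        Sequence of (mean, variance) tuples, e.g. from
        :func:`variance_trace_from_pointscan`.

    Returns
    -------
    DetectorModel
        With standard errors on slope and intercept from the retained points.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < min_points:
        raise InvalidDataError(f"need >= {min_points} (mean, variance) pairs")
    if np.any(arr[:, 1] < 0):
        raise InvalidDataError("negative variance in calibration data")
    if np.any(arr[:, 0] < 0):
        raise InvalidDataError("negative mean in calibration data")

    order = np.argsort(arr[:, 0])
    x = arr[order, 0]
    y = arr[order, 1]
    if np.ptp(x) == 0:
        raise DegenerateFitError("all calibration means identical")

    # scale used to decide whether an exact fit is "perfect" in float terms
    atol = 1e-9 * max(1.0, float(np.max(np.abs(y))))

    k = min_points
    while k < len(x):
        slope, intercept, _, _, resid = _ols_line(x[:k], y[:k])
        rmse = np.sqrt(np.mean(resid**2))
        pred_next = intercept + slope * x[k]
        err_next = abs(y[k] - pred_next)
        sst = np.sum((y[:k] - y[:k].mean()) ** 2)
        ssr = np.sum(resid**2)
        r2 = 1.0 if sst <= atol**2 else 1.0 - ssr / sst
        if r2 < r2_min:
            break
        if err_next > max(outlier_sigma * rmse, atol):
            break
        k += 1

    slope, intercept, se_s, se_i, _ = _ols_line(x[:k], y[:k])
    return DetectorModel(
        slope=max(slope, 0.0),
        intercept=max(intercept, 0.0),
        linear_max=float(x[k - 1]),
        saturation=saturation if np.isfinite(saturation) else max(float(x[-1]), float(x[k - 1])),
        stderr_slope=float(se_s),
        stderr_intercept=float(se_i),
    )


def variance_trace_from_pointscan(
    trace: Sequence[float], window: int
) -> list[tuple[float, float]]:
    """Reduce a uniform-illumination point-scan trace to (mean, variance) pairs.

    The trace is cut into non-overlapping windows; each window yields its
    sample mean and sample variance (ddof=1). Feeds :func:`fit_detector_noise`.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if window < 16:
        raise ValueError("window must be >= 16 samples")
    if window > len(trace):
        raise ValueError("window longer than trace")
    nwin = len(trace) // window
    chunks = trace[: nwin * window].reshape(nwin, window)
    means = chunks.mean(axis=1)
    variances = chunks.var(axis=1, ddof=1)
    return list(zip(means.tolist(), variances.tolist()))
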