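"""Monomeric-brightness calibration and MEU normalization.

Every oligomerization measurement needs an independent monomeric yardstick:
the quantal brightness of a sample known to be monomeric (membrane-anchored
monomeric GFP, or single dye molecules bound to glass), measured under the
same acquisition settings. Brightnesses are then expressed in monomeric
equivalent units (MEU) — multiples of that control — so a pure dimer reads
~2 MEU. Calibrations are keyed by an acquisition tag and never mixed across
imaging-condition sets.

Also fits the surface-density-vs-solution-concentration curve of dye
monolayer preparations with a saturating single exponential
``D(c) = D_max (1 - exp(-c / c0))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import IncompatibleCalibrationError, InsufficientDataError

__all__ = [
    "CalibrationResult",
    "MeuValue",
    "build_monomer_control",
    "normalize_to_meu",
    "fit_density_concentration",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Monomeric quantal brightness defining 1 MEU for one acquisition setting."""

    eps_monomer: float
    sem: float
    n_cells: int
    acquisition_tag: str = "default"
    outlier_flags: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.eps_monomer <= 0:
            raise ValueError("eps_monomer must be > 0")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "eps_monomer": self.eps_monomer,
                    "sem": self.sem,
                    "n_cells": self.n_cells,
                    "acquisition_tag": self.acquisition_tag,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "CalibrationResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass(frozen=True)
class MeuValue:
    value: float
    err: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("MEU value must be >= 0")


def build_monomer_control(
    per_cell_eps: Sequence[tuple[float, float] | float],
    acquisition_tag: str = "default",
    outlier_sd: float = 3.0,
) -> CalibrationResult:
    """Pool per-cell monomer brightnesses into the 1-MEU control.

    Takes (eps, err) pairs or bare eps values, one per cell; returns the
    unweighted mean with the SEM across cells. Cells deviating by more than
    ``outlier_sd`` robust standard deviations (1.4826 * MAD about the
    median, so a bright aggregate cannot mask itself) are flagged but not
    removed.
    """
    eps = np.array([p[0] if np.ndim(p) else p for p in per_cell_eps], dtype=float)
    if len(eps) < 3:
        raise InsufficientDataError("monomer control needs >= 3 cells")
    mean = float(eps.mean())
    sem = float(eps.std(ddof=1)) / np.sqrt(len(eps))
    robust_sd = 1.4826 * float(np.median(np.abs(eps - np.median(eps))))
    if robust_sd > 0:
        flags = tuple(
            np.nonzero(np.abs(eps - np.median(eps)) > outlier_sd * robust_sd)[0].tolist()
        )
    else:
        flags = ()
    return CalibrationResult(
        eps_monomer=mean, sem=float(sem), n_cells=len(eps),
        acquisition_tag=acquisition_tag, outlier_flags=flags,
    )


def normalize_to_meu(
    eps: float,
    err: float,
    cal: CalibrationResult,
    acquisition_tag: str | None = None,
) -> MeuValue:
    """Express a brightness in monomeric equivalent units.

    value = eps / eps_monomer, with first-order error propagation in
    quadrature over the sample error and the calibration SEM.
    """
    if acquisition_tag is not None and acquisition_tag != cal.acquisition_tag:
        raise IncompatibleCalibrationError(
            f"brightness from {acquisition_tag!r} cannot use the "
            f"{cal.acquisition_tag!r} calibration"
        )
    value = eps / cal.eps_monomer
    rel2 = 0.0
    if eps > 0:
        rel2 += (err / eps) ** 2
    rel2 += (cal.sem / cal.eps_monomer) ** 2
    return MeuValue(value=float(value), err=float(value * np.sqrt(rel2)))


def fit_density_concentration(
    pairs: Sequence[tuple[float, float]],
) -> dict:
    """Fit the monolayer surface-density calibration curve D(c) = D_max (1 - e^{-c/c0}).

    Surface binding of dye conjugates saturates sterically at high solution
    concentration; at low c the curve is linear with slope D_max/c0.
    Returns D_max, c0 with standard errors from the fit covariance.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or len(arr) < 4:
        raise InsufficientDataError("need >= 4 (concentration, density) pairs")
    c, d = arr[:, 0], arr[:, 1]
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")

    def curve(c, dmax, c0):
        return dmax * (1.0 - np.exp(-c / c0))

    p0 = (float(d.max()) * 1.2 + 1e-9, float(np.median(c)))
    popt, pcov = curve_fit(curve, c, d, p0=p0, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    resid = d - curve(c, *popt)
    return {
        "D_max": float(popt[0]),
        "c0": float(popt[1]),
        "stderr_D_max": float(perr[0]),
        "stderr_c0": float(perr[1]),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }
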