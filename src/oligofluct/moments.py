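"""Spatial intensity moment analysis of single fluorescence images.

For a spatial Poisson field of point emitters blurred by a Gaussian PSF, the
pixel-intensity cumulants are additive over independent populations
(Campbell's theorem)::

    kappa_n = gamma_n * sum_i N_i * eps_i**n,      gamma_n = 1/n (2D Gaussian)

with ``N_i`` entities per beam area and ``eps_i`` their quantal brightness.
One population is solved in closed form from the mean and kappa_2; two
populations (and their brightness ratio alpha = eps2/eps1) require the first
four cumulants and a numerical inversion.

Measured moments carry the analog detector's shot-noise contribution. Under
the calibrated conditional-Gaussian law ``M = I + eta``,
``eta | I ~ N(0, c + s I)``, the measured cumulants relate to the noise-free
ones through::

    kappa2_M = kappa2 + c + s*kappa1
    kappa3_M = kappa3 + 3 s kappa2
    kappa4_M = kappa4 + 6 s kappa3 + 3 s**2 kappa2

(obtained from the CGF identity K_M(t) = c t^2/2 + K_I(t + s t^2/2)); the
correction chain inverts these top-down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidDataError, NoSignalError
from .psf_detector import DetectorModel, PsfModel, shape_factor

__all__ = [
    "RoiSpec",
    "MomentSet",
    "TwoPopulationResult",
    "estimate_background",
    "compute_raw_moments",
    "correct_moments",
    "forward_cumulants",
    "solve_one_population",
    "solve_two_populations",
    "moments_from_image",
]

MIN_SIGNAL_PIXELS = 64


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest, 0-based half-open pixel coordinates."""

    row0: int
    col0: int
    height: int
    width: int
    role: str = "signal"  # "signal" | "background"

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must have positive extent")
        if self.role not in ("signal", "background"):
            raise ValueError("role must be 'signal' or 'background'")

    @property
    def area(self) -> int:
        return self.height * self.width

    def pixels(self, image: np.ndarray) -> np.ndarray:
        if (
            self.row0 < 0
            or self.col0 < 0
            or self.row0 + self.height > image.shape[0]
            or self.col0 + self.width > image.shape[1]
        ):
            raise InvalidDataError("ROI extends beyond image bounds")
        return np.asarray(
            image[self.row0 : self.row0 + self.height, self.col0 : self.col0 + self.width],
            dtype=float,
        )


@dataclass(frozen=True)
class MomentSet:
    """Background-corrected mean and noise-corrected spatial cumulants of an ROI."""

    mean: float
    kappa2: float
    kappa3: float
    kappa4: float
    n_pixels: int
    raw_mu2: float
    raw_mu3: float
    raw_mu4: float
    over_corrected: bool = False


@dataclass(frozen=True)
class TwoPopulationResult:
    N1: float
    eps1: float
    N2: float
    eps2: float
    converged: bool
    residual: float
    model: str = "two"  # "two" | "one" (fallback)

    @property
    def alpha(self) -> float:
        """Brightness ratio eps2/eps1 (>= 1 by the output ordering)."""
        return self.eps2 / self.eps1 if self.eps1 > 0 else np.inf


def estimate_background(
    image: np.ndarray,
    background_rois: Optional[Sequence[RoiSpec]] = None,
    auto_fraction: float = 0.05,
) -> float:
    """Mean background intensity, from dark ROIs or the darkest pixels.

    With explicit ROIs: plain mean over their pixels. In auto mode (no ROIs):
    mean of the darkest ``auto_fraction`` of the image, a proxy for the
    "empty dark regions" a user would otherwise outline by hand.
    """
    image = np.asarray(image, dtype=float)
    if background_rois is not None:
        rois = [r for r in background_rois if r.role == "background"] or list(background_rois)
        if not rois:
            raise InvalidDataError("empty background ROI list")
        vals = np.concatenate([r.pixels(image).ravel() for r in rois])
        return float(vals.mean())
    flat = np.sort(image.ravel())
    k = max(1, int(round(auto_fraction * flat.size)))
    return float(flat[:k].mean())


def compute_raw_moments(pixels: np.ndarray) -> tuple[float, float, float, float]:
    """Sample mean and plain central moments mu2..mu4 of the ROI pixel values."""
    v = np.asarray(pixels, dtype=float).ravel()
    if v.size < MIN_SIGNAL_PIXELS:
        raise InvalidDataError(f"need >= {MIN_SIGNAL_PIXELS} pixels, got {v.size}")
    mean = v.mean()
    d = v - mean
    d2 = d * d
    mu2 = d2.mean()
    mu3 = (d2 * d).mean()
    mu4 = (d2 * d2).mean()
    return float(mean), float(mu2), float(mu3), float(mu4)


def correct_moments(
    mean: float,
    mu2: float,
    mu3: float,
    mu4: float,
    n_pixels: int,
    detector: Optional[DetectorModel] = None,
    background: float = 0.0,
) -> MomentSet:
    """Remove the detector's shot-noise contribution from measured moments.

    ``mean`` is the background-subtracted ROI mean; ``background`` is the
    offset that was subtracted, needed because the noise variance follows the
    *raw* signal level ``mean + background``.
    """
    m4c = mu4 - 3.0 * mu2 * mu2  # measured 4th cumulant
    if detector is None or (detector.slope == 0 and detector.intercept == 0):
        k2, k3, k4 = mu2, mu3, m4c
        flagged = k2 < 0
    else:
        s = detector.slope
        noise_var = detector.variance(mean + background)
        k2 = mu2 - noise_var
        k3 = mu3 - 3.0 * s * k2
        k4 = m4c - 6.0 * s * k3 - 3.0 * s * s * k2
        flagged = k2 < 0
    return MomentSet(
        mean=float(mean),
        kappa2=float(k2),
        kappa3=float(k3),
        kappa4=float(k4),
        n_pixels=int(n_pixels),
        raw_mu2=float(mu2),
        raw_mu3=float(mu3),
        raw_mu4=float(mu4),
        over_corrected=bool(flagged),
    )


def forward_cumulants(
    N: Sequence[float], eps: Sequence[float], psf: Optional[PsfModel] = None
) -> tuple[float, float, float, float]:
    """Analytic cumulants kappa_1..kappa_4 of a compound Poisson mixture."""
    N = np.asarray(N, dtype=float)
    eps = np.asarray(eps, dtype=float)
    gam = [1.0 / n for n in range(1, 5)] if psf is None else [shape_factor(psf, n) for n in range(1, 5)]
    return tuple(float(g * np.sum(N * eps**n)) for n, g in zip(range(1, 5), gam))


def solve_one_population(m: MomentSet, psf: PsfModel) -> tuple[float, float]:
    """Closed-form (N, eps) for a single population from mean and kappa2."""
    if m.kappa2 <= 0:
        raise NoSignalError("kappa2 <= 0 after noise correction: no resolvable signal")
    if m.mean <= 0:
        raise NoSignalError("non-positive mean intensity")
    g2 = shape_factor(psf, 2)
    eps = m.kappa2 / (g2 * m.mean)
    return m.mean / eps, eps


def _two_pop_residuals(
    logp: np.ndarray, kappas: np.ndarray, scales: np.ndarray, alpha_fixed: Optional[float]
) -> np.ndarray:
    if alpha_fixed is None:
        n1, e1, n2, e2 = np.exp(logp)
    else:
        n1, e1, n2 = np.exp(logp)
        e2 = alpha_fixed * e1
    orders = np.arange(1, len(kappas) + 1)
    model = (n1 * e1**orders + n2 * e2**orders) / orders
    return (model - kappas) / scales


def _solve_fixed_brightnesses(
    m: MomentSet, e1: float, e2: float, fallback_ratio: float
) -> TwoPopulationResult:
    """Densities for known brightnesses: kappa1, kappa2 are linear in (N1, N2)."""
    A = np.array([[e1, e2], [e1**2 / 2.0, e2**2 / 2.0]])
    rhs = np.array([m.mean, m.kappa2])
    n1, n2 = np.linalg.solve(A, rhs)
    n1, n2 = max(n1, 0.0), max(n2, 0.0)
    kappas = np.array([m.mean, m.kappa2, m.kappa3, m.kappa4])
    orders = np.arange(1, 5)
    scales = np.maximum(np.abs(kappas), np.abs(m.mean) ** orders * 1e-9)
    model = (n1 * e1**orders + n2 * e2**orders) / orders
    res = float(np.linalg.norm((model - kappas) / scales))
    return TwoPopulationResult(
        N1=float(n1), eps1=float(e1), N2=float(n2), eps2=float(e2),
        converged=True, residual=res, model="two",
    )


def solve_two_populations(
    m: MomentSet,
    psf: PsfModel,
    fix_alpha: Optional[float] = None,
    fix_eps1: Optional[float] = None,
    fallback_ratio: float = 0.5,
) -> TwoPopulationResult:
    """Invert the first four cumulants for a two-population mixture.

    Solves ``kappa_n = gamma_n (N1 eps1^n + N2 eps2^n)``, n = 1..4, by damped
    least squares in log-parameter space, multi-started over brightness
    ratios {1.5, 2, 4, 8} crossed with monomer-heavy / oligomer-heavy
    intensity splits. With ``fix_alpha`` the tie eps2 = alpha*eps1 removes
    one parameter; three cumulants would then suffice to pose the system,
    but all four are still used — the 3-equation system can have multiple
    positive roots and kappa4 disambiguates. Falls back to the
    one-population solution (N2 = 0) when the two-population fit does not
    beat it by ``fallback_ratio``.

    The free and fixed-alpha inversions are exact on noise-free cumulants
    but fragile on measured ones: the fixed-alpha system restricted to
    kappa_1..kappa_3 has two positive roots that only kappa_4 separates, and
    kappa_4 carries by far the largest sampling error. Supplying the
    independently calibrated monomeric brightness as ``fix_eps1`` (with
    ``fix_alpha`` for a monomer-oligomer model) reduces the problem to a
    well-conditioned linear solve on kappa_1, kappa_2 — the recommended
    pipeline whenever a monomeric control exists.
    """
    if m.kappa2 <= 0:
        raise NoSignalError("kappa2 <= 0: cannot analyze fluctuations")
    if fix_eps1 is not None:
        if fix_alpha is None:
            raise ValueError("fix_eps1 requires fix_alpha (a monomer-oligomer model)")
        return _solve_fixed_brightnesses(m, fix_eps1, fix_alpha * fix_eps1, fallback_ratio)
    n_eq = 4
    kappas = np.array([m.mean, m.kappa2, m.kappa3, m.kappa4][:n_eq])
    if not np.all(np.isfinite(kappas)):
        raise InvalidDataError("non-finite cumulants")
    # relative scaling; guard against vanishing higher cumulants
    orders = np.arange(1, n_eq + 1)
    scales = np.maximum(np.abs(kappas), np.abs(m.mean) ** orders * 1e-9)

    N0, e0 = solve_one_population(m, psf)
    one_res = float(
        np.linalg.norm(_two_pop_residuals(np.log([N0, e0, 1e-12]), kappas, scales, 1.0))
    )

    starts = []
    alphas = [fix_alpha] if fix_alpha is not None else [1.5, 2.0, 4.0, 8.0]
    for a in alphas:
        for f1 in (0.8, 0.2):  # fraction of the mean carried by the dim population
            e1 = 2.0 * e0 / (1.0 + a)
            e2 = a * e1
            n1 = max(f1 * m.mean / e1, 1e-8)
            n2 = max((1.0 - f1) * m.mean / e2, 1e-8)
            starts.append((n1, e1, n2) if fix_alpha is not None else (n1, e1, n2, e2))

    best = None
    for start in starts:
        sol = least_squares(
            _two_pop_residuals,
            np.log(start),
            args=(kappas, scales, fix_alpha),
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
            max_nfev=4000,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    if fix_alpha is None:
        n1, e1, n2, e2 = np.exp(best.x)
    else:
        n1, e1, n2 = np.exp(best.x)
        e2 = fix_alpha * e1
    if e2 < e1:  # enforce eps1 <= eps2 ordering
        n1, e1, n2, e2 = n2, e2, n1, e1
    two_res = float(np.sqrt(2.0 * best.cost))
    converged = bool(best.success and two_res < 1e-3)

    # an (absolute) tiny one-population residual means the mixture is
    # indistinguishable from a single population: report it as such
    one_pop_data = one_res < 1e-8 or e2 / max(e1, 1e-300) < 1.02
    if one_pop_data or two_res > fallback_ratio * one_res or not np.isfinite(two_res):
        return TwoPopulationResult(
            N1=N0, eps1=e0, N2=0.0, eps2=e0, converged=True, residual=one_res, model="one"
        )
    return TwoPopulationResult(
        N1=float(n1), eps1=float(e1), N2=float(n2), eps2=float(e2),
        converged=converged, residual=two_res, model="two",
    )


def moments_from_image(
    image: np.ndarray,
    signal_rois: Optional[Sequence[RoiSpec]] = None,
    detector: Optional[DetectorModel] = None,
    background: float = 0.0,
    tile: int = 128,
    tile_overlap: float = 0.5,
    tile_mean_tolerance: float = 0.5,
) -> MomentSet:
    """Noise-corrected moment set of an image (or its signal ROIs).

    Large ROIs are subdivided into overlapping square tiles; per-tile moments
    are computed about each tile's own mean (suppressing slow spatial
    gradients), tiles whose mean deviates from the median tile mean by more
    than ``tile_mean_tolerance`` (fractional) are discarded as heterogeneous,
    and the surviving tiles' moment estimates are averaged before the
    detector-noise correction.
    """
    image = np.asarray(image, dtype=float)
    if signal_rois is None:
        signal_rois = [RoiSpec(0, 0, image.shape[0], image.shape[1])]
    blocks = []
    for roi in signal_rois:
        if roi.role != "signal":
            continue
        px = roi.pixels(image)
        step = max(1, int(tile * (1.0 - tile_overlap)))
        if px.shape[0] >= 2 * tile and px.shape[1] >= 2 * tile:
            for r in range(0, px.shape[0] - tile + 1, step):
                for c in range(0, px.shape[1] - tile + 1, step):
                    blocks.append(px[r : r + tile, c : c + tile])
        else:
            blocks.append(px)
    if not blocks:
        raise InvalidDataError("no signal ROI pixels")

    stats = np.array([compute_raw_moments(b) for b in blocks])
    med = np.median(stats[:, 0])
    if med > 0 and len(blocks) > 2:
        keep = np.abs(stats[:, 0] - med) <= tile_mean_tolerance * med
        if keep.any():
            stats = stats[keep]
    mean, mu2, mu3, mu4 = stats.mean(axis=0)
    n_pixels = int(sum(b.size for b in blocks))
    return correct_moments(
        mean - background, mu2, mu3, mu4, n_pixels, detector=detector, background=background
    )
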