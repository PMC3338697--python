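"""Spatial intensity distribution analysis (SpIDA).

SpIDA fits the pixel-intensity histogram of a single image with a
super-Poissonian model: the intensity at a pixel is the sum of the
PSF-weighted contributions of a Poisson-distributed number of particles in
the surrounding region, so the pixel-value distribution is a compound
Poisson law built from the single-particle intensity distribution rho(k)
(the intensity a particle at a uniformly random position contributes to the
pixel). Weighting every particle-number configuration by its Poisson
probability gives the model histogram

    H(k) = sum_n  Poisson(n; lambda) * rho^{*n}(k)

and two independent populations convolve: H = H_1 * H_2. An analog PMT
broadens the histogram further — each intensity value is smeared by a
Gaussian whose variance follows the calibrated linear law. Fitting the
broadened model to the observed histogram recovers the particle density N
(per beam area) and the quantal brightness eps concurrently.

Numerically the compound law is evaluated either by direct Poisson-weighted
convolution (small lambda) or through the characteristic function,
``H_hat = exp(lambda * (rho_hat - 1))``, on a grid fine enough that intensity
quantization happens once, after compounding. The detector broadening has an
exact characteristic-function form under the linear variance law
(``E e^{i xi M} = e^{-c xi^2/2} G_I(i xi - s xi^2 / 2)``), which the fitting
path uses; the standalone histogram-smearing operation is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.special import ndtr

import lmfit

from .errors import InvalidDataError, PrecisionError, ResourceLimitError
from .moments import RoiSpec, correct_moments
from .psf_detector import DetectorModel, PsfModel

__all__ = [
    "IntensityHistogram",
    "HistogramModel",
    "SpidaFitOptions",
    "SpidaFitResult",
    "single_particle_distribution",
    "compound_histogram",
    "model_histogram",
    "convolve_histograms",
    "broaden_histogram",
    "image_to_histogram",
    "fit_histogram",
]

DEFAULT_CUTOFF_FACTOR = 3.0  # cutoff disc radius in units of w0
_NORM_TOL = 1e-9


@dataclass
class IntensityHistogram:
    """Observed pixel-intensity counts on integer 1-iu bins starting at k=0."""

    counts: np.ndarray
    background_subtracted: bool = True
    n_saturated: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise InvalidDataError("histogram counts must be >= 0")

    @property
    def total_pixels(self) -> int:
        return int(round(self.counts.sum()))

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def mean(self) -> float:
        k = np.arange(len(self.counts))
        return float(np.sum(k * self.frequencies))

    def variance(self) -> float:
        k = np.arange(len(self.counts))
        m = self.mean()
        return float(np.sum((k - m) ** 2 * self.frequencies))


@dataclass
class HistogramModel:
    """Model probability mass over integer intensity bins k = 0, 1, ..."""

    pmf: np.ndarray
    params: dict = field(default_factory=dict)
    broadened: bool = False

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if np.any(self.pmf < -1e-12):
            raise InvalidDataError("model mass must be >= 0")
        self.pmf = np.clip(self.pmf, 0.0, None)
        total = self.pmf.sum()
        if abs(total - 1.0) > 1e-6:
            raise InvalidDataError(f"model mass sums to {total}, expected 1")
        self.pmf /= total

    def mean(self) -> float:
        return float(np.sum(np.arange(len(self.pmf)) * self.pmf))

    def variance(self) -> float:
        k = np.arange(len(self.pmf))
        m = self.mean()
        return float(np.sum((k - m) ** 2 * self.pmf))


@dataclass(frozen=True)
class SpidaFitOptions:
    """Model choice and fit window for a SpIDA histogram fit.

    ``monomer_dimer`` ties eps2 = 2*eps1 (no quenching between subunits);
    eps1 is fixed to ``fixed_monomer_eps`` when given, otherwise fitted
    jointly with the two densities.
    """

    model: str = "one_pop"  # one_pop | two_pop_free | monomer_dimer
    fixed_monomer_eps: Optional[float] = None
    k_range: Optional[tuple[int, int]] = None
    weighting: str = "none"  # none | poisson

    def __post_init__(self) -> None:
        if self.model not in ("one_pop", "two_pop_free", "monomer_dimer"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.weighting not in ("none", "poisson"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass
class SpidaFitResult:
    model: str
    params: dict           # name -> value
    stderr: dict           # name -> asymptotic standard error (may be nan)
    residual: float        # sum of squared frequency residuals in the window
    fitted: np.ndarray     # model pmf over the fit window's bins
    k_range: tuple[int, int]
    n_pixels: int
    success: bool
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _auto_bin_width(populations: Sequence[tuple[float, float]]) -> float:
    """Sub-integer grid where quantization is coarse on the relevant scale.

    Per-particle grid quantization matters when either a single particle's
    brightness is only a few bins (eps < 16) or the whole compound
    distribution is narrow (SD < 40 iu) so that sub-bin structure survives
    into the output. Wide distributions smear quantization out and can use
    the cheaper 1-iu grid.
    """
    active = [(N, e) for N, e in populations if N > 0 and e > 0]
    if not active:
        return 1.0
    if min(e for _, e in active) < 16.0:
        return 0.25
    sd = np.sqrt(0.5 * sum(N * e**2 for N, e in active))
    return 0.25 if sd < 40.0 else 1.0


def single_particle_distribution(
    psf: PsfModel,
    eps: float,
    cutoff_radius: Optional[float] = None,
    bin_width: float = 1.0,
    subsample: Optional[int] = None,
) -> np.ndarray:
    """Intensity distribution of one particle uniform in the cutoff disc.

    A particle at distance d contributes ``eps * exp(-2 d^2 / w0^2)`` to the
    observed pixel; over a uniformly random position in the disc of radius
    ``cutoff_radius`` (default 3 w0) the probability that the contribution
    falls in intensity bin j is the area of the corresponding annulus between
    Gaussian-profile contours, divided by the disc area — computed here in
    closed form. Passing ``subsample`` instead estimates the same masses on a
    Cartesian grid with that many sample points per pixel width (the slow
    cross-check used in tests).

    Returns the probability masses on bins of ``bin_width`` iu; the carried
    reference area is the disc area ``pi * cutoff_radius**2``.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    w0 = psf.e2_radius
    if cutoff_radius is None:
        cutoff_radius = DEFAULT_CUTOFF_FACTOR * w0
    if cutoff_radius < DEFAULT_CUTOFF_FACTOR * w0 - 1e-12:
        raise ValueError("cutoff_radius must be >= 3 w0")
    # fraction of the particle's total intensity beyond the cutoff
    if np.exp(-2.0 * cutoff_radius**2 / w0**2) > 1e-3:
        raise PrecisionError("cutoff disc too small for 0.1% mass closure")

    disc_area = np.pi * cutoff_radius**2

    if subsample is not None:
        step = psf.pixel_size / subsample
        half = int(np.ceil(cutoff_radius / step))
        g = (np.arange(-half, half + 1) + 0.5) * step
        yy, xx = np.meshgrid(g, g, indexing="ij")
        r2 = yy**2 + xx**2
        inside = r2 <= cutoff_radius**2
        contrib = eps * np.exp(-2.0 * r2[inside] / w0**2)
        j = np.rint(contrib / bin_width).astype(int)
        pmf = np.bincount(j, minlength=int(round(eps / bin_width)) + 1).astype(float)
        return pmf / pmf.sum()

    jmax = int(np.rint(eps / bin_width))
    edges = (np.arange(jmax + 2) - 0.5) * bin_width  # bin j covers [edges[j], edges[j+1])
    # area (within the disc) where the contribution is >= x
    with np.errstate(divide="ignore"):
        r2_of = np.where(
            edges >= eps,
            0.0,
            np.minimum(
                (w0**2 / 2.0) * np.log(np.maximum(eps / np.maximum(edges, 1e-300), 1.0)),
                cutoff_radius**2,
            ),
        )
    area_ge = np.pi * r2_of
    area_ge[edges <= 0] = disc_area
    pmf = (area_ge[:-1] - area_ge[1:]) / disc_area
    pmf[0] += 1.0 - pmf.sum()  # closure: sub-threshold area belongs to bin 0
    return pmf


def _shift_pmf(pmf: np.ndarray, frac_bins: float) -> np.ndarray:
    """Shift a pmf by a (possibly fractional) number of grid cells.

    The fractional part is realized by linear interpolation between adjacent
    cells: the mean shifts exactly, at the price of a negligible
    ``frac*(1-frac)`` cell^2 of added variance.
    """
    if frac_bins == 0.0:
        return pmf
    whole = int(np.floor(frac_bins))
    frac = frac_bins - whole
    out = np.zeros(len(pmf) + whole + 1)
    out[whole : whole + len(pmf)] += (1.0 - frac) * pmf
    out[whole + 1 : whole + 1 + len(pmf)] += frac * pmf
    return out


def _aggregate_to_integer_bins(
    fine: np.ndarray,
    bin_width: float,
    shift: int = 0,
    saturation: float = np.inf,
) -> np.ndarray:
    """Collapse a fine-grid pmf (index*bin_width - shift*bin_width) to 1-iu bins.

    Each fine cell represents the intensity interval
    ``(u - shift -/+ 1/2) * bin_width``; its mass is split between the
    integer bins ``[k - 1/2, k + 1/2)`` it overlaps, proportionally to
    overlap length, so coarse-graining is unbiased.
    """
    centers = (np.arange(len(fine)) - shift) * bin_width
    lo = centers - 0.5 * bin_width
    hi = centers + 0.5 * bin_width
    k_lo = np.floor(lo + 0.5).astype(np.int64)
    k_hi = np.floor(hi + 0.5 - 1e-12).astype(np.int64)
    straddle = k_hi > k_lo
    w_lo = np.where(straddle, (k_lo + 0.5 - lo) / bin_width, 1.0)
    k1 = np.clip(k_lo, 0, None)
    k2 = np.clip(k_hi, 0, None)
    if np.isfinite(saturation):
        k1 = np.minimum(k1, int(saturation))
        k2 = np.minimum(k2, int(saturation))
    nbins = int(max(k1.max(), k2.max())) + 1
    out = np.bincount(k1, weights=fine * w_lo, minlength=nbins)
    out += np.bincount(k2, weights=fine * (1.0 - w_lo), minlength=nbins)
    return out


def _compound_fine_pmf(
    populations: Sequence[tuple[float, float]],
    psf: PsfModel,
    detector: Optional[DetectorModel],
    cutoff_factor: float,
    bin_width: float,
) -> tuple[np.ndarray, int]:
    """Fine-grid pmf of the (optionally detector-broadened) compound field.

    Returns (pmf, shift): index u corresponds to intensity
    (u - shift)*bin_width. Uses the characteristic function throughout;
    exact up to grid resolution.

    Grid-quantizing the single-particle distribution sheds a small
    deterministic amount of mean intensity per particle (the sub-cell PSF
    tail); it is restored by shifting rho itself, so that a pixel's total
    correction scales with its in-disc particle count and truly empty
    pixels stay at zero.
    """
    w0 = psf.e2_radius
    R = cutoff_factor * w0
    rhos = []
    lams = []
    for N, eps in populations:
        if N < 0 or eps < 0:
            raise ValueError("N and eps must be >= 0")
        if N == 0 or eps == 0:
            continue
        rho = single_particle_distribution(psf, eps, R, bin_width=bin_width)
        lam = N * (np.pi * R**2) / psf.beam_area
        rho_mean_iu = bin_width * float(np.sum(np.arange(len(rho)) * rho))
        deficit_per_particle = max((N * eps / lam) - rho_mean_iu, 0.0)
        rho = _shift_pmf(rho, deficit_per_particle / bin_width)
        rhos.append(rho)
        lams.append(lam)

    c = detector.intercept if detector is not None else 0.0
    s = detector.slope if detector is not None else 0.0
    cp = c / bin_width**2            # dark variance in index units
    sp = s / bin_width               # slope in index units

    # grid size from the compound mean/variance plus noise and shift margins
    mean_idx = sum(l * np.sum(np.arange(len(r)) * r) for l, r in zip(lams, rhos))
    var_idx = sum(l * np.sum(np.arange(len(r)) ** 2 * r) for l, r in zip(lams, rhos))
    var_idx += cp + sp * mean_idx
    jtop = max((len(r) for r in rhos), default=1)
    shift = int(np.ceil(10.0 * np.sqrt(cp + 1.0))) + 4 if detector is not None else 0
    L = next_fast_len(int(np.ceil(mean_idx + 14.0 * np.sqrt(var_idx) + jtop + shift + 32)))
    if L > 2**24:
        raise ResourceLimitError(f"model grid of {L} bins exceeds the sanity bound")

    # numpy's irfft inverts the forward convention sum_u p_u e^{-i xi u}
    xi = 2.0 * np.pi * np.arange(L // 2 + 1) / L
    z = -1j * xi - 0.5 * sp * xi**2
    log_cf = -0.5 * cp * xi**2 + 0j
    for lam, rho in zip(lams, rhos):
        j = np.arange(len(rho))
        rho_hat = np.exp(np.outer(z, j)) @ rho
        log_cf += lam * (rho_hat - 1.0)
    cf = np.exp(log_cf)
    if shift:
        cf *= np.exp(-1j * xi * shift)
    pmf = irfft(cf, L)
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    return pmf, shift


def model_histogram(
    populations: Sequence[tuple[float, float]],
    psf: PsfModel,
    detector: Optional[DetectorModel] = None,
    cutoff_factor: float = DEFAULT_CUTOFF_FACTOR,
    bin_width: Optional[float] = None,
    saturation: float = np.inf,
) -> HistogramModel:
    """Broadened (or ideal) model histogram for up to two populations.

    ``populations`` is a list of (N per beam area, eps) pairs. This is the
    fitting path: compounding and detector broadening happen in one
    characteristic-function pass and intensities are quantized to integer
    bins once, at the end.
    """
    eps_vals = [e for _, e in populations if e > 0]
    if bin_width is None:
        bin_width = _auto_bin_width(populations)
    if not eps_vals or all(N == 0 for N, _ in populations):
        pmf = np.zeros(1)
        pmf[0] = 1.0
        if detector is not None and (detector.intercept > 0 or detector.slope > 0):
            return broaden_histogram(HistogramModel(pmf, params={"populations": []}), detector)
        return HistogramModel(pmf, params={"populations": []})
    fine, shift = _compound_fine_pmf(populations, psf, detector, cutoff_factor, bin_width)
    pmf = _aggregate_to_integer_bins(fine, bin_width, shift, saturation)
    return HistogramModel(
        pmf,
        params={"populations": [tuple(p) for p in populations], "cutoff_factor": cutoff_factor},
        broadened=detector is not None,
    )


def compound_histogram(
    N: float,
    eps: float,
    psf: PsfModel,
    cutoff_factor: float = DEFAULT_CUTOFF_FACTOR,
    bin_width: Optional[float] = None,
    method: str = "auto",
) -> HistogramModel:
    """Single-population super-Poissonian model histogram (no detector).

    ``method`` selects direct Poisson-sum convolution or characteristic-
    function multiplication; 'auto' switches to the CF route when the
    expected particle count in the cutoff disc exceeds 30.
    """
    if N < 0 or eps < 0:
        raise ValueError("N and eps must be >= 0")
    if N == 0 or eps == 0:
        return HistogramModel(np.array([1.0]), params={"N": N, "eps": eps})
    if bin_width is None:
        bin_width = _auto_bin_width([(N, eps)])
    R = cutoff_factor * psf.e2_radius
    lam = N * (np.pi * R**2) / psf.beam_area
    if method == "auto":
        method = "cf" if lam > 30 else "direct"
    if method == "cf":
        fine, shift = _compound_fine_pmf([(N, eps)], psf, None, cutoff_factor, bin_width)
        pmf = _aggregate_to_integer_bins(fine, bin_width, shift)
    elif method == "direct":
        rho = single_particle_distribution(psf, eps, R, bin_width=bin_width)
        deficit = max(eps * psf.beam_area / (np.pi * R**2)
                      - bin_width * float(np.sum(np.arange(len(rho)) * rho)), 0.0)
        rho = _shift_pmf(rho, deficit / bin_width)
        mean_idx = lam * np.sum(np.arange(len(rho)) * rho)
        var_idx = lam * np.sum(np.arange(len(rho)) ** 2 * rho)
        L = int(np.ceil(mean_idx + 14 * np.sqrt(var_idx) + len(rho) + 32))
        fine = np.zeros(L)
        term = np.zeros(L)
        term[0] = 1.0  # rho^{*0}
        weight = np.exp(-lam)  # Poisson(0)
        fine += weight * term
        cum = weight
        n = 0
        while cum < 1.0 - _NORM_TOL and n < 10 * lam + 200:
            n += 1
            term = np.convolve(term, rho)[:L]
            weight *= lam / n
            fine += weight * term
            cum += weight
        fine /= fine.sum()
        pmf = _aggregate_to_integer_bins(fine, bin_width)
    else:
        raise ValueError(f"unknown method {method!r}")
    return HistogramModel(pmf, params={"N": N, "eps": eps, "lambda_cutoff": lam})


def convolve_histograms(h1: HistogramModel, h2: HistogramModel) -> HistogramModel:
    """Histogram of the summed intensity of two independent populations."""
    pmf = np.convolve(h1.pmf, h2.pmf)
    return HistogramModel(
        pmf,
        params={"convolved": (h1.params, h2.params)},
        broadened=h1.broadened or h2.broadened,
    )


def broaden_histogram(h: HistogramModel, detector: DetectorModel) -> HistogramModel:
    """Smear each histogram bin by the detector's Gaussian noise kernel.

    Bin k's mass is redistributed as a Gaussian centered at k with variance
    ``intercept + slope * k`` discretized on the integer grid; mass landing
    at or below zero accumulates in bin 0. Total mass is preserved.
    """
    pmf = h.pmf
    if detector.slope == 0 and detector.intercept == 0:
        return HistogramModel(pmf.copy(), params=dict(h.params), broadened=True)
    k = np.arange(len(pmf))
    sig = np.sqrt(np.maximum(detector.variance(k), 1e-300))
    kmax_out = int(np.ceil(len(pmf) - 1 + 8.0 * sig[-1])) + 1
    out = np.zeros(kmax_out)
    nz = np.nonzero(pmf > 1e-16)[0]
    for i in nz:
        s = sig[i]
        if s < 1e-12:
            out[i] += pmf[i]
            continue
        lo = max(0, int(np.floor(i - 8 * s)))
        hi = min(kmax_out - 1, int(np.ceil(i + 8 * s)))
        edges = np.arange(lo, hi + 2) - 0.5
        cdf = ndtr((edges - i) / s)
        cell = np.diff(cdf)
        cell[0] = cdf[1] if lo == 0 else cell[0]   # fold the sub-zero tail into bin 0
        cell[-1] += 1.0 - cdf[-1]                   # and the upper tail into the top cell
        out[lo : hi + 1] += pmf[i] * cell
    return HistogramModel(out, params=dict(h.params), broadened=True)


# ---------------------------------------------------------------------------
# observed histograms and fitting
# ---------------------------------------------------------------------------

def image_to_histogram(
    image: np.ndarray,
    rois: Optional[Sequence[RoiSpec]] = None,
    background: float = 0.0,
    saturation: float = np.inf,
) -> IntensityHistogram:
    """Histogram of background-subtracted pixel values over signal ROIs.

    Negative background-subtracted values clamp to bin 0; pixels at or above
    ``saturation`` are counted and flagged but kept in the top bin.
    """
    image = np.asarray(image, dtype=float)
    if rois is None:
        vals = image.ravel()
    else:
        sig = [r for r in rois if r.role == "signal"]
        if not sig:
            raise InvalidDataError("no signal ROI given")
        vals = np.concatenate([r.pixels(image).ravel() for r in sig])
    if vals.size == 0:
        raise InvalidDataError("empty ROI")
    n_sat = int(np.sum(vals >= saturation)) if np.isfinite(saturation) else 0
    shifted = np.clip(np.rint(vals - background), 0, None).astype(np.int64)
    counts = np.bincount(shifted)
    return IntensityHistogram(counts, background_subtracted=True, n_saturated=n_sat)


def _moments_init(
    observed: IntensityHistogram, psf: PsfModel, detector: Optional[DetectorModel]
) -> tuple[float, float]:
    """Cheap one-population (N, eps) start from the histogram's mean/variance."""
    mu = observed.mean()
    var = observed.variance()
    ms = correct_moments(mu, var, 0.0, 0.0, observed.total_pixels, detector=detector)
    k2 = max(ms.kappa2, 0.05 * var, 1e-6)
    eps = 2.0 * k2 / max(mu, 1e-9)
    return max(mu / eps, 1e-6), eps


def fit_histogram(
    observed: IntensityHistogram,
    options: SpidaFitOptions,
    psf: PsfModel,
    detector: Optional[DetectorModel] = None,
    init: Optional[dict] = None,
    min_pixels: int = 10_000,
) -> SpidaFitResult:
    """Least-squares fit of the broadened model histogram to an observed one.

    The observed histogram is normalized to frequencies; the model pmf is
    evaluated over the fit window (default: up to the 99.9th percentile of
    the observed intensities) and compared bin-by-bin, unweighted by default.
    Initialization comes from moment analysis of the histogram itself unless
    an explicit ``init`` mapping is given. Deterministic given the init.
    """
    flags: list[str] = []
    counts = observed.counts.copy()
    if observed.total_pixels < min_pixels:
        raise InvalidDataError(f"need >= {min_pixels} pixels for a stable histogram fit")
    if observed.n_saturated > 0.01 * observed.total_pixels:
        flags.append("saturation")
        counts[-1] = 0.0

    freq = counts / counts.sum()
    if options.k_range is not None:
        k_lo, k_hi = options.k_range
    else:
        cdf = np.cumsum(freq)
        k_lo, k_hi = 0, int(np.searchsorted(cdf, 0.999)) + 1
    k_hi = min(k_hi, len(freq) - 1)
    window = np.arange(k_lo, k_hi + 1)
    target = freq[window]
    if options.weighting == "poisson":
        sigma = np.sqrt(np.maximum(counts[window], 1.0)) / counts.sum()
    else:
        sigma = np.ones_like(target)

    N0, e0 = _moments_init(observed, psf, detector)
    init = dict(init or {})

    params = lmfit.Parameters()
    if options.model == "one_pop":
        params.add("N1", value=init.get("N1", N0), min=1e-8)
        params.add("eps1", value=init.get("eps1", e0), min=1e-6)
    elif options.model == "two_pop_free":
        params.add("N1", value=init.get("N1", 0.7 * N0), min=1e-8)
        params.add("eps1", value=init.get("eps1", 0.7 * e0), min=1e-6)
        params.add("N2", value=init.get("N2", 0.3 * N0), min=1e-8)
        params.add("eps2", value=init.get("eps2", 2.0 * e0), min=1e-6)
    else:  # monomer_dimer
        if options.fixed_monomer_eps is not None:
            params.add("eps1", value=options.fixed_monomer_eps, vary=False)
            e_ref = options.fixed_monomer_eps
        else:
            params.add("eps1", value=init.get("eps1", 0.7 * e0), min=1e-6)
            e_ref = 0.7 * e0
        params.add("N1", value=init.get("N1", max(0.5 * N0 * e0 / e_ref, 1e-6)), min=1e-8)
        params.add("N2", value=init.get("N2", max(0.25 * N0 * e0 / e_ref, 1e-6)), min=1e-8)

    def populations(p) -> list[tuple[float, float]]:
        if options.model == "one_pop":
            return [(p["N1"].value, p["eps1"].value)]
        if options.model == "two_pop_free":
            return [(p["N1"].value, p["eps1"].value), (p["N2"].value, p["eps2"].value)]
        e1 = p["eps1"].value
        return [(p["N1"].value, e1), (p["N2"].value, 2.0 * e1)]

    def residual(p) -> np.ndarray:
        model = model_histogram(populations(p), psf, detector=detector).pmf
        padded = np.zeros(k_hi + 1)
        upto = min(len(model), k_hi + 1)
        padded[:upto] = model[:upto]
        return (padded[window] - target) / sigma

    minres = lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")
    values = {name: float(minres.params[name].value) for name in minres.params}
    stderr = {
        name: (float(minres.params[name].stderr) if minres.params[name].stderr else float("nan"))
        for name in minres.params
    }
    if options.model == "monomer_dimer":
        values["eps2"] = 2.0 * values["eps1"]
    fitted_pmf = model_histogram(populations(minres.params), psf, detector=detector).pmf
    padded = np.zeros(k_hi + 1)
    upto = min(len(fitted_pmf), k_hi + 1)
    padded[:upto] = fitted_pmf[:upto]
    if not minres.success:
        flags.append("non-converged")
    return SpidaFitResult(
        model=options.model,
        params=values,
        stderr=stderr,
        residual=float(np.sum((padded[window] - target) ** 2)),
        fitted=padded[window],
        k_range=(int(k_lo), int(k_hi)),
        n_pixels=observed.total_pixels,
        success=bool(minres.success),
        flags=tuple(flags),
    )
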