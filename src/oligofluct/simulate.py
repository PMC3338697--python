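"""Synthetic confocal image generator for fluorophore-tagged membrane proteins.

The forward model emulates a single-channel CLSM image of a 2D membrane:

1. point emitters (oligomeric entities) are scattered by a spatial Poisson
   process at a given surface density, with a guard margin beyond the image
   edges so edge pixels see unbiased statistics;
2. each entity of oligomer order ``n`` carries ``Binomial(n, label_fraction)``
   fluorophores, each contributing the per-subunit quantal brightness;
3. the ideal image samples the Gaussian PSF at pixel centers — pixel value is
   the sum over entities of ``brightness * exp(-2 d^2 / w0^2)``;
4. the analog detector adds conditionally Gaussian noise with the calibrated
   variance law, clamps at saturation and digitizes to integer intensity units.

The generator is the ground-truth oracle used to validate the moment and
histogram analyses: the rendered field is an exact compound Poisson process
whose spatial cumulants are ``kappa_n = gamma_n * sum_i N_i eps_i^n``
(densities N per beam area).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ResourceLimitError
from .psf_detector import DetectorModel, PsfModel

__all__ = [
    "PopulationSpec",
    "SimulationSpec",
    "place_particles",
    "render_image",
    "apply_detector",
    "simulate_image",
    "simulate_bleach_series",
    "write_tiff",
]

_GUARD_FACTOR = 3.0  # guard margin beyond the field, in units of w0
_PATCH_FACTOR = 3.0  # render cutoff radius, in units of w0 (exp(-18) truncation)
_MAX_EXPECTED_PARTICLES = 1e8


@dataclass(frozen=True)
class PopulationSpec:
    """One oligomeric population of fluorescent entities.

    ``surface_density`` counts entities (not subunits) per µm²;
    ``oligomer_order`` is the number of subunits per entity; each subunit is
    fluorescently labeled with probability ``label_fraction``.
    """

    surface_density: float
    oligomer_order: int = 1
    per_subunit_brightness: float = 1.0
    label_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.surface_density < 0:
            raise ValueError("surface_density must be >= 0")
        if int(self.oligomer_order) != self.oligomer_order or self.oligomer_order < 1:
            raise ValueError("oligomer_order must be a positive integer")
        if self.per_subunit_brightness < 0:
            raise ValueError("per_subunit_brightness must be >= 0")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must be in [0, 1]")

    def density_per_beam_area(self, psf: PsfModel) -> float:
        """Entities per beam area (the N of the moment/histogram models)."""
        return self.surface_density * psf.beam_area


@dataclass(frozen=True)
class SimulationSpec:
    image_shape: tuple[int, int]
    pixel_size: float
    psf: PsfModel
    populations: tuple[PopulationSpec, ...]
    background: float = 0.0
    detector: Optional[DetectorModel] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) < 64:
            raise ValueError("image_shape must be at least 64 x 64")
        if self.pixel_size != self.psf.pixel_size:
            raise ValueError("pixel_size must match psf.pixel_size")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        object.__setattr__(self, "populations", tuple(self.populations))

    def to_json(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["detector"] = dataclasses.asdict(self.detector) if self.detector else None
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=float)


def _field_bounds(spec: SimulationSpec) -> tuple[float, float]:
    """Height/width of the particle field (image plus guard band), in µm."""
    guard = _GUARD_FACTOR * spec.psf.e2_radius
    h = spec.image_shape[0] * spec.pixel_size + 2 * guard
    w = spec.image_shape[1] * spec.pixel_size + 2 * guard
    return h, w


def place_particles(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw Poisson-distributed entity positions and their total brightnesses.

    Returns ``(positions, brightness)``: positions are (M, 2) continuous
    (row, col) coordinates in µm relative to the image origin (guard-band
    particles have coordinates outside [0, extent]); brightness is the entity
    total, ``per_subunit_brightness * Binomial(order, label_fraction)``.
    """
    positions, counts, eps = _place_with_counts(spec, rng)
    return positions, counts.astype(float) * eps


def _place_with_counts(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """As place_particles but keeping per-entity fluorophore counts.

    Returns (positions, fluorophore_counts, per_subunit_brightness_per_entity);
    the count granularity is what photobleaching thins.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = _field_bounds(spec)
    guard = _GUARD_FACTOR * spec.psf.e2_radius
    area = h * w

    expected = sum(p.surface_density for p in spec.populations) * area
    if expected > _MAX_EXPECTED_PARTICLES:
        raise ResourceLimitError(
            f"expected particle count {expected:.3g} exceeds {_MAX_EXPECTED_PARTICLES:.0g}"
        )

    pos_list, cnt_list, eps_list = [], [], []
    for pop in spec.populations:
        m = rng.poisson(pop.surface_density * area)
        pos = np.empty((m, 2))
        pos[:, 0] = rng.uniform(-guard, h - guard, size=m)
        pos[:, 1] = rng.uniform(-guard, w - guard, size=m)
        counts = rng.binomial(pop.oligomer_order, pop.label_fraction, size=m)
        pos_list.append(pos)
        cnt_list.append(counts)
        eps_list.append(np.full(m, pop.per_subunit_brightness))
    if not pos_list:
        return np.empty((0, 2)), np.empty(0, dtype=int), np.empty(0)
    return np.concatenate(pos_list), np.concatenate(cnt_list), np.concatenate(eps_list)


def _render_kernel_py(positions, brightness, ny, nx, pixel_size, w0, wpix, img):
    inv = 2.0 / (w0 * w0)
    r2max = (_PATCH_FACTOR * w0) ** 2
    for p in range(positions.shape[0]):
        py = positions[p, 0]
        px = positions[p, 1]
        b = brightness[p]
        iy = int(round(py / pixel_size - 0.5))
        ix = int(round(px / pixel_size - 0.5))
        for dy in range(-wpix, wpix + 1):
            ry = iy + dy
            if ry < 0 or ry >= ny:
                continue
            cy = (ry + 0.5) * pixel_size
            dy2 = (cy - py) ** 2
            for dx in range(-wpix, wpix + 1):
                rx = ix + dx
                if rx < 0 or rx >= nx:
                    continue
                cx = (rx + 0.5) * pixel_size
                d2 = dy2 + (cx - px) ** 2
                if d2 <= r2max:
                    img[ry, rx] += b * np.exp(-inv * d2)


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _render_kernel = njit(cache=False, fastmath=False)(_render_kernel_py)
except Exception:  # pragma: no cover
    _render_kernel = None


def render_image(
    particles: tuple[np.ndarray, np.ndarray],
    psf: PsfModel,
    shape: tuple[int, int],
    pixel_size: float,
    chunk: int = 8192,
) -> np.ndarray:
    """Render the ideal (noise-free, real-valued) image of point emitters.

    Pixel (r, c) has its center at ((r + 0.5) px, (c + 0.5) px); each particle
    deposits ``brightness * exp(-2 d^2 / w0^2)`` on pixels within 3 w0 of its
    position (the truncated tail carries an e^-18 fraction of the profile).
    """
    positions, brightness = particles
    positions = np.ascontiguousarray(np.asarray(positions, dtype=float).reshape(-1, 2))
    brightness = np.ascontiguousarray(np.asarray(brightness, dtype=float).ravel())
    ny, nx = shape
    if len(positions) == 0:
        return np.zeros(shape)

    keep = brightness > 0
    positions = positions[keep]
    brightness = brightness[keep]
    w0 = psf.e2_radius

    if _render_kernel is not None:
        img2 = np.zeros((ny, nx))
        wpix = int(np.ceil(_PATCH_FACTOR * w0 / pixel_size))
        _render_kernel(positions, brightness, ny, nx, pixel_size, w0, wpix, img2)
        return img2

    img = np.zeros(ny * nx)
    wpix = int(np.ceil(_PATCH_FACTOR * w0 / pixel_size))
    offs = np.arange(-wpix, wpix + 1)
    doy, dox = np.meshgrid(offs, offs, indexing="ij")
    doy = doy.ravel()
    dox = dox.ravel()
    inv = 2.0 / w0**2

    for lo in range(0, len(positions), chunk):
        py = positions[lo : lo + chunk, 0]
        px = positions[lo : lo + chunk, 1]
        b = brightness[lo : lo + chunk]
        iy = np.round(py / pixel_size - 0.5).astype(np.int64)
        ix = np.round(px / pixel_size - 0.5).astype(np.int64)
        # pixel-center coordinates of the whole patch, per particle
        cy = (iy[:, None] + doy[None, :] + 0.5) * pixel_size
        cx = (ix[:, None] + dox[None, :] + 0.5) * pixel_size
        d2 = (cy - py[:, None]) ** 2 + (cx - px[:, None]) ** 2
        contrib = b[:, None] * np.exp(-inv * d2)
        ry = iy[:, None] + doy[None, :]
        rx = ix[:, None] + dox[None, :]
        ok = (ry >= 0) & (ry < ny) & (rx >= 0) & (rx < nx) & (d2 <= (_PATCH_FACTOR * w0) ** 2)
        flat = (ry * nx + rx)[ok]
        img += np.bincount(flat, weights=contrib[ok], minlength=ny * nx)
    return img.reshape(shape)


def apply_detector(
    ideal: np.ndarray,
    detector: Optional[DetectorModel],
    background: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Digitize an ideal image through the analog detector model.

    Per pixel: Gaussian draw with mean ``ideal + background`` and variance
    ``intercept + slope * (ideal + background)``, clamped to
    ``[0, saturation]`` and rounded to the nearest integer intensity unit.
    A ``None`` detector is noiseless (round only).
    """
    signal = np.asarray(ideal, dtype=float) + background
    if detector is not None and detector.slope == 0 and detector.intercept == 0:
        noisy = signal
    elif detector is None:
        noisy = signal
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        sd = np.sqrt(detector.variance(signal))
        noisy = signal + rng.standard_normal(signal.shape) * sd
    sat = detector.saturation if detector is not None else np.inf
    out = np.clip(np.rint(noisy), 0, sat)
    if np.isfinite(sat) and sat <= np.iinfo(np.uint16).max:
        return out.astype(np.uint16)
    return out.astype(np.int64)


def simulate_image(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Full forward simulation: place, render, digitize. Deterministic per seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    particles = place_particles(spec, rng)
    ideal = render_image(particles, spec.psf, spec.image_shape, spec.pixel_size)
    return apply_detector(ideal, spec.detector, spec.background, rng=rng)


def simulate_bleach_series(
    spec: SimulationSpec,
    n_frames: int,
    survival_per_frame: float,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate an irreversible photobleaching image series.

    Frame 0 is the pristine field; before each subsequent frame every
    fluorophore independently survives with probability
    ``survival_per_frame``, so frame ``i`` has expected fluorophore density
    ``survival**i`` of the initial while the per-fluorophore brightness is
    untouched. Positions are fixed (fixed sample, no diffusion).
    """
    if not 0.0 < survival_per_frame <= 1.0:
        raise ValueError("survival_per_frame must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    positions, counts, eps = _place_with_counts(spec, rng)
    frames = np.empty((n_frames, *spec.image_shape), dtype=np.int64)
    for i in range(n_frames):
        ideal = render_image(
            (positions, counts.astype(float) * eps),
            spec.psf,
            spec.image_shape,
            spec.pixel_size,
        )
        frames[i] = apply_detector(ideal, spec.detector, spec.background, rng=rng)
        if survival_per_frame < 1.0:
            counts = rng.binomial(counts, survival_per_frame)
    return frames


def write_tiff(path: str, image: np.ndarray, spec: Optional[SimulationSpec] = None) -> None:
    """Write a (single- or multi-page) 16-bit TIFF plus a JSON sidecar of the spec."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
    if spec is not None:
        spec.to_json(str(path) + ".json")
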