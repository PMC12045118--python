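"""Stereo stimulus geometry: disparity profiles, textures, and rendering.

Deterministic computations defining the stimuli of the depth-manipulated
surround-suppression experiments: pixel/degree conversion for the display,
the quantized cumulative-Gaussian disparity bump, region-averaged disparities
of its surround, the non-oriented filtered-noise texture, and stereo-pair
rendering in which disparity is realized as an integer-pixel horizontal
shift applied to the right eye only.

All angles are in degrees of visual angle under the linear small-angle
pixel-pitch convention (screen width in degrees divided by width in pixels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "MonitorGeometry",
    "BumpSpec",
    "DisparityProfile",
    "px_to_deg",
    "deg_to_px",
    "default_radial_grid",
    "bump_profile",
    "flat_top_diameter",
    "region_mean_disparity",
    "make_nonoriented_texture",
    "orientation_energy",
    "michelson_contrast",
    "Scene",
    "GratingPatch",
    "AnnulusGrating",
    "TexturePatch",
    "DotSquare",
    "BumpGrating",
    "render_stereo_pair",
    "write_png",
]

Weighting = Literal["radial_unweighted", "area_weighted", "ring_level_mean"]


@dataclass(frozen=True)
class MonitorGeometry:
    """Display geometry of the stereoscope monitor."""

    width_deg: float = 36.5
    width_px: int = 1600
    height_deg: float = 27.4
    height_px: int = 1200
    viewing_distance_cm: float = 54.0

    def __post_init__(self) -> None:
        if self.width_deg <= 0 or self.width_px <= 0:
            raise ValueError("monitor geometry must have positive width")

    @property
    def pixel_pitch_deg(self) -> float:
        """Degrees of visual angle per pixel (linear convention)."""
        return self.width_deg / self.width_px


def px_to_deg(pixels: float | np.ndarray, geometry: MonitorGeometry | None = None):
    """Convert a signed pixel count to degrees of visual angle."""
    geom = geometry or MonitorGeometry()
    return pixels * geom.pixel_pitch_deg


def deg_to_px(degrees: float | np.ndarray, geometry: MonitorGeometry | None = None):
    """Convert degrees to the nearest integer pixel count (half away from 0)."""
    geom = geometry or MonitorGeometry()
    raw = np.asarray(degrees, dtype=float) / geom.pixel_pitch_deg
    px = np.sign(raw) * np.floor(np.abs(raw) + 0.5)
    out = px.astype(int)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Disparity bump
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BumpSpec:
    """Parameters of the smooth 3D bump stimulus.

    The bump is a cumulative-Gaussian disparity profile in radial
    coordinates, normalized to run from 0 disparity at the center to
    ``base_disparity_deg`` (negative, i.e. behind fixation for the base
    relative to the top pointing toward the observer) at the base.
    ``cdf_mean_radius_deg`` places the Gaussian mean at the flat-top radius
    plus two steepness sigmas, so the disparity magnitude stays below half a
    pixel everywhere inside the nominal flat top.
    """

    flat_top_diameter_deg: float = 2.26
    steepness_sigma_deg: float = 0.5
    base_disparity_deg: float = -0.5
    geometry: MonitorGeometry = field(default_factory=MonitorGeometry)

    def __post_init__(self) -> None:
        if self.base_disparity_deg >= 0:
            raise ValueError("base_disparity_deg must be negative (uncrossed)")
        if self.steepness_sigma_deg <= 0:
            raise ValueError("steepness_sigma_deg must be positive")

    @property
    def cdf_mean_radius_deg(self) -> float:
        return self.flat_top_diameter_deg / 2.0 + 2.0 * self.steepness_sigma_deg


@dataclass(frozen=True)
class DisparityProfile:
    """Radial disparity function of the bump plus its pixel quantization."""

    radii: np.ndarray
    disparity_deg: np.ndarray
    disparity_px_quantized: np.ndarray
    pixel_pitch_deg: float

    @property
    def ring_levels(self) -> tuple[int, ...]:
        """Sorted distinct nonzero quantized disparity values (pixels)."""
        levels = np.unique(self.disparity_px_quantized)
        return tuple(int(v) for v in levels if v != 0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "radius_deg": self.radii,
                "disparity_deg": self.disparity_deg,
                "disparity_px": self.disparity_px_quantized,
            }
        )


def default_radial_grid(max_radius_deg: float = 4.0, n: int = 40001) -> np.ndarray:
    return np.linspace(0.0, max_radius_deg, n)


def bump_profile(
    spec: BumpSpec,
    r_samples: np.ndarray | None = None,
    quantization: Literal["floor_magnitude", "nearest"] = "floor_magnitude",
) -> DisparityProfile:
    """Evaluate the bump's disparity profile on a radial grid.

    Continuous form: ``d(r) = base * Phi((r - cdf_mean_radius) / sigma)``
    (the 1-CDF construction after normalization to [base, 0]).  Pixel
    quantization defaults to the floor of the disparity magnitude, which
    makes the default bump a stack of exactly 21 one-pixel disparity rings
    (|base| is 21.9 px; rounding to nearest would create a 22nd).
    """
    r = default_radial_grid() if r_samples is None else np.asarray(r_samples, float)
    if r.ndim != 1 or np.any(r < 0):
        raise ValueError("r_samples must be a 1-D nonnegative array")
    if np.any(np.diff(r) < 0):
        raise ValueError("r_samples must be sorted ascending")
    d = spec.base_disparity_deg * norm.cdf(
        (r - spec.cdf_mean_radius_deg) / spec.steepness_sigma_deg
    )
    pitch = spec.geometry.pixel_pitch_deg
    mag_px = np.abs(d) / pitch
    if quantization == "floor_magnitude":
        q = np.floor(mag_px)
    elif quantization == "nearest":
        q = np.floor(mag_px + 0.5)
    else:
        raise ValueError(f"unknown quantization rule {quantization!r}")
    q = (np.sign(d) * q).astype(int)
    return DisparityProfile(
        radii=r, disparity_deg=d, disparity_px_quantized=q, pixel_pitch_deg=pitch
    )


def flat_top_diameter(profile: DisparityProfile) -> float:
    """Diameter of the perceptually flat top of the bump.

    Measured as the region whose continuous disparity magnitude is below
    half a pixel -- the part of the surface that nearest-pixel rendering
    displays at zero disparity.
    """
    flat = np.abs(profile.disparity_deg) / profile.pixel_pitch_deg < 0.5
    if not flat.any():
        return 0.0
    return 2.0 * float(profile.radii[flat].max())


def region_mean_disparity(
    profile: DisparityProfile,
    inner_r: float,
    outer_r: float,
    weighting: Weighting = "area_weighted",
) -> tuple[float, int]:
    """Mean disparity of the bump over an annular region.

    Conventions (the published region averages do not pin down a unique
    one, so all three are exposed):

    - ``area_weighted`` (default): mean of the continuous disparity weighted
      by annulus area (weight proportional to radius).  This reproduces the
      published 1-degree-ring average of about -5 px.
    - ``radial_unweighted``: plain mean over the radial samples.
    - ``ring_level_mean``: mean over the distinct quantized disparity levels
      present in the region (including a zero level if present); the
      convention closest to the published whole-bump average of -10 px.

    Returns ``(mean_deg, mean_px)`` with the pixel value rounded to the
    nearest integer.
    """
    if not inner_r < outer_r:
        raise ValueError("inner_r must be smaller than outer_r")
    mask = (profile.radii >= inner_r) & (profile.radii <= outer_r)
    if not mask.any():
        raise ValueError("region contains no profile samples")
    r = profile.radii[mask]
    d = profile.disparity_deg[mask]
    if weighting == "radial_unweighted":
        mean_deg = float(d.mean())
    elif weighting == "area_weighted":
        mean_deg = float((d * r).sum() / r.sum())
    elif weighting == "ring_level_mean":
        levels = np.unique(profile.disparity_px_quantized[mask])
        mean_deg = float(levels.mean()) * profile.pixel_pitch_deg
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    mean_px = int(np.sign(mean_deg) * np.floor(abs(mean_deg) / profile.pixel_pitch_deg + 0.5))
    return mean_deg, mean_px


# ---------------------------------------------------------------------------
# Non-oriented texture
# ---------------------------------------------------------------------------


def _gabor_bank_transfer(
    shape: tuple[int, int],
    sf_cyc_per_deg: float,
    n_orientations: int,
    pitch_deg: float,
    bandwidth_octaves: float = 1.0,
) -> np.ndarray:
    """Summed frequency-domain transfer of an oriented Gabor filter bank.

    Each filter is band-pass at ``sf_cyc_per_deg`` with a 1-octave
    (half-magnitude) spatial-frequency bandwidth and a Gaussian orientation
    envelope; orientations are equally spaced over 0-180 degrees.
    """
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pitch_deg)[:, None]
    fx = np.fft.fftfreq(nx, d=pitch_deg)[None, :]
    b = 2.0**bandwidth_octaves
    # circular Gaussian envelope: one isotropic frequency-domain blob per
    # orientation at +/- the center frequency; sigma set by the half-
    # magnitude octave bandwidth
    sigma_f = sf_cyc_per_deg * (b - 1) / ((b + 1) * math.sqrt(2 * math.log(2)))
    transfer = np.zeros(shape)
    for k in range(n_orientations):
        t_k = k * math.pi / n_orientations
        cx, cy = sf_cyc_per_deg * math.cos(t_k), sf_cyc_per_deg * math.sin(t_k)
        for sx, sy in ((cx, cy), (-cx, -cy)):
            transfer += np.exp(-((fx - sx) ** 2 + (fy - sy) ** 2) / (2 * sigma_f**2))
    return transfer


def make_nonoriented_texture(
    size_px: tuple[int, int],
    sf_cyc_per_deg: float = 2.0,
    n_orientations: int = 18,
    target_contrast: float = 80.0,
    geometry: MonitorGeometry | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Filtered-noise texture with isotropic orientation content.

    Seeded Gaussian noise is filtered through a bank of ``n_orientations``
    oriented Gabor filters (equally spaced over 0-180 deg) centered at
    ``sf_cyc_per_deg``; the summed output is rescaled so the 0.1-99.9
    luminance percentiles span the target Michelson contrast about mean
    luminance 0.5, then clipped to that range.  Identical seeds give
    identical images.
    """
    if not 0 < target_contrast <= 100:
        raise ValueError("target_contrast must be in (0, 100]")
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    ny, nx = size_px
    if ny <= 0 or nx <= 0:
        raise ValueError("size_px must be positive")
    geom = geometry or MonitorGeometry()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((ny, nx))
    transfer = _gabor_bank_transfer(
        (ny, nx), sf_cyc_per_deg, n_orientations, geom.pixel_pitch_deg
    )
    filtered = np.fft.ifft2(np.fft.fft2(noise) * transfer).real
    filtered -= filtered.mean()
    lo, hi = np.percentile(filtered, [0.1, 99.9])
    half_span = max((hi - lo) / 2.0, 1e-12)
    amplitude = target_contrast / 200.0  # Michelson C about mean 0.5
    img = 0.5 + (filtered - (lo + hi) / 2.0) * (amplitude / half_span)
    return np.clip(img, 0.5 - amplitude, 0.5 + amplitude)


def michelson_contrast(image: np.ndarray) -> float:
    """(Lmax - Lmin) / (Lmax + Lmin), in percent."""
    lo, hi = float(image.min()), float(image.max())
    return 100.0 * (hi - lo) / (hi + lo)


def orientation_energy(
    image: np.ndarray,
    n_bins: int = 18,
    sf_cyc_per_deg: float = 2.0,
    geometry: MonitorGeometry | None = None,
) -> np.ndarray:
    """Fourier energy profile over orientation within the stimulus passband.

    Returns the mean power per frequency coefficient in each of ``n_bins``
    orientation bins (mean rather than sum, so uneven lattice coverage of
    the bins does not masquerade as anisotropy).  Used as an isotropy
    oracle: a non-oriented texture has a near-flat profile (small
    coefficient of variation), a single-orientation texture a strongly
    peaked one.
    """
    geom = geometry or MonitorGeometry()
    ny, nx = image.shape
    fy = np.fft.fftfreq(ny, d=geom.pixel_pitch_deg)[:, None]
    fx = np.fft.fftfreq(nx, d=geom.pixel_pitch_deg)[None, :]
    f = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx) % math.pi
    power = np.abs(np.fft.fft2(image - image.mean())) ** 2
    band = (f > sf_cyc_per_deg / 2) & (f < sf_cyc_per_deg * 2)
    bins = np.minimum((theta[band] / (math.pi / n_bins)).astype(int), n_bins - 1)
    totals = np.bincount(bins, weights=power[band], minlength=n_bins)
    counts = np.maximum(np.bincount(bins, minlength=n_bins), 1)
    return totals / counts


# ---------------------------------------------------------------------------
# Scene elements and stereo rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GratingPatch:
    """Circular sine-wave grating patch."""

    center_deg: tuple[float, float] = (0.0, 0.0)
    diameter_deg: float = 2.0
    orientation_deg: float = 45.0
    sf_cyc_per_deg: float = 2.0
    contrast: float = 30.0
    phase_deg: float = 0.0
    disparity_deg: float = 0.0


@dataclass(frozen=True)
class AnnulusGrating:
    """Annular grating surround, optionally cut into wedges by radial slots."""

    center_deg: tuple[float, float] = (0.0, 0.0)
    inner_diameter_deg: float = 2.0
    outer_diameter_deg: float = 8.0
    orientation_deg: float = 45.0
    sf_cyc_per_deg: float = 2.0
    contrast: float = 80.0
    phase_deg: float = 0.0
    disparity_deg: float = 0.0
    n_wedges: int = 0  # 0 -> full annulus
    slot_width_deg: float = 0.33
    slot_angle_deg: float = 45.0


@dataclass(frozen=True)
class TexturePatch:
    """Disc or annulus filled with the non-oriented filtered-noise texture."""

    center_deg: tuple[float, float] = (0.0, 0.0)
    inner_diameter_deg: float = 0.0
    outer_diameter_deg: float = 8.0
    contrast: float = 80.0
    sf_cyc_per_deg: float = 2.0
    n_orientations: int = 18
    disparity_deg: float = 0.0


@dataclass(frozen=True)
class DotSquare:
    """Random-dot square (fixation-lock element)."""

    center_deg: tuple[float, float]
    side_deg: float = 1.1
    dot_density: float = 0.5
    disparity_deg: float = 0.0


@dataclass(frozen=True)
class BumpGrating:
    """Annular grating whose disparity follows the quantized bump profile:
    one ring per quantized pixel level, each shifted by its own disparity."""

    spec: BumpSpec
    inner_diameter_deg: float = 2.0
    outer_diameter_deg: float = 8.0
    orientation_deg: float = 45.0
    sf_cyc_per_deg: float = 2.0
    contrast: float = 80.0
    phase_deg: float = 0.0


Element = GratingPatch | AnnulusGrating | TexturePatch | DotSquare | BumpGrating


@dataclass(frozen=True)
class Scene:
    """Declarative stimulus description: elements composited in list order
    (later elements painted over earlier ones) on a mid-gray background."""

    elements: tuple[Element, ...]
    size_px: tuple[int, int] = (600, 600)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))


def _grids(size_px: tuple[int, int], geom: MonitorGeometry):
    ny, nx = size_px
    pitch = geom.pixel_pitch_deg
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    return np.meshgrid(x, y)


def _grating_values(xx, yy, orientation_deg, sf, contrast, phase_deg):
    th = math.radians(orientation_deg)
    # coordinate along the grating's modulation axis (perpendicular to bars)
    u = xx * math.sin(th) + yy * math.cos(th)
    return 0.5 * (
        1.0 + contrast / 100.0 * np.sin(2 * math.pi * sf * u + math.radians(phase_deg))
    )


def _element_layer(
    el: Element, size_px: tuple[int, int], geom: MonitorGeometry, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Render an element to one or more (values, mask, disparity_deg) layers."""
    xx, yy = _grids(size_px, geom)
    if isinstance(el, GratingPatch):
        cx, cy = el.center_deg
        r = np.hypot(xx - cx, yy - cy)
        mask = r <= el.diameter_deg / 2.0
        vals = _grating_values(
            xx - cx, yy - cy, el.orientation_deg, el.sf_cyc_per_deg, el.contrast, el.phase_deg
        )
        return [(vals, mask, el.disparity_deg)]
    if isinstance(el, AnnulusGrating):
        cx, cy = el.center_deg
        r = np.hypot(xx - cx, yy - cy)
        mask = (r >= el.inner_diameter_deg / 2.0) & (r <= el.outer_diameter_deg / 2.0)
        if el.n_wedges:
            half = el.slot_width_deg / 2.0
            a = math.radians(el.slot_angle_deg)
            u = (xx - cx) * math.cos(a) + (yy - cy) * math.sin(a)
            v = -(xx - cx) * math.sin(a) + (yy - cy) * math.cos(a)
            mask &= (np.abs(u) > half) & (np.abs(v) > half)
        vals = _grating_values(
            xx - cx, yy - cy, el.orientation_deg, el.sf_cyc_per_deg, el.contrast, el.phase_deg
        )
        return [(vals, mask, el.disparity_deg)]
    if isinstance(el, TexturePatch):
        cx, cy = el.center_deg
        r = np.hypot(xx - cx, yy - cy)
        mask = (r >= el.inner_diameter_deg / 2.0) & (r <= el.outer_diameter_deg / 2.0)
        vals = make_nonoriented_texture(
            size_px,
            sf_cyc_per_deg=el.sf_cyc_per_deg,
            n_orientations=el.n_orientations,
            target_contrast=el.contrast,
            geometry=geom,
            seed=int(rng.integers(2**31)),
        )
        return [(vals, mask, el.disparity_deg)]
    if isinstance(el, DotSquare):
        cx, cy = el.center_deg
        half = el.side_deg / 2.0
        mask = (np.abs(xx - cx) <= half) & (np.abs(yy - cy) <= half)
        vals = (rng.random(size_px) < el.dot_density).astype(float)
        return [(vals, mask, el.disparity_deg)]
    if isinstance(el, BumpGrating):
        profile = bump_profile(el.spec)
        r = np.hypot(xx, yy)
        vals = _grating_values(
            xx, yy, el.orientation_deg, el.sf_cyc_per_deg, el.contrast, el.phase_deg
        )
        pitch = geom.pixel_pitch_deg
        layers = []
        ring = (r >= el.inner_diameter_deg / 2.0) & (r <= el.outer_diameter_deg / 2.0)
        levels = [0] + list(profile.ring_levels)
        # radius band of each quantized level from the dense profile
        for level in levels:
            sel = profile.disparity_px_quantized == level
            if not sel.any():
                continue
            r_lo, r_hi = profile.radii[sel].min(), profile.radii[sel].max()
            mask = ring & (r >= r_lo) & (r <= r_hi)
            if mask.any():
                layers.append((vals, mask, level * pitch))
        return layers
    raise TypeError(f"unknown scene element {type(el).__name__}")


def render_stereo_pair(
    scene: Scene, geometry: MonitorGeometry | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Render left- and right-eye images of a scene.

    The left eye sees every element at zero disparity; in the right eye each
    element is shifted horizontally by its disparity rounded to integer
    pixels (negative/uncrossed disparity shifts leftward).  Random elements
    (dot patterns, textures) are drawn once and shared between the eyes, so
    a zero-disparity scene renders two identical images.
    """
    geom = geometry or MonitorGeometry()
    ny, nx = scene.size_px
    half_w = nx * geom.pixel_pitch_deg / 2.0
    half_h = ny * geom.pixel_pitch_deg / 2.0
    left = np.full(scene.size_px, 0.5)
    right = np.full(scene.size_px, 0.5)
    rng = np.random.default_rng(seed)
    for el in scene.elements:
        cx, cy = getattr(el, "center_deg", (0.0, 0.0))
        extent = getattr(el, "outer_diameter_deg", None) or getattr(
            el, "diameter_deg", None
        ) or getattr(el, "side_deg", 0.0)
        if abs(cx) + extent / 2.0 > half_w + 1e-9 or abs(cy) + extent / 2.0 > half_h + 1e-9:
            raise ValueError(
                f"element {type(el).__name__} extends outside the {ny}x{nx} px frame"
            )
        for vals, mask, disp_deg in _element_layer(el, scene.size_px, geom, rng):
            left[mask] = vals[mask]
            shift = deg_to_px(disp_deg, geom)
            vals_s = np.roll(vals, shift, axis=1)
            mask_s = np.roll(mask, shift, axis=1)
            right[mask_s] = vals_s[mask_s]
    return left, right


def write_png(image: np.ndarray, path) -> None:
    """Save a [0, 1] luminance image as 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
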