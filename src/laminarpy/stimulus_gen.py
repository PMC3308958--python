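"""Occluded object stimuli and their low-level image statistics.

Object drawings are viewed through circular apertures on a hexagonal grid
(2 deg diameter, 0.7-1.0 deg gaps, within a +/-7.6 deg square field); the
scrambled condition rotates the content of every object-containing aperture
by an angle drawn with equal probability from uniform [60, 120] deg or
uniform [-120, -60] deg, for a mean absolute rotation of 90 deg. Because
rotation about the aperture centre permutes pixels within the circle, the
per-aperture RMS contrast is preserved up to interpolation — the premise
that intact and scrambled stimuli deliver the same contrast to each
visual-field location.

Since the original object image set is not redistributable, "objects" here
are procedurally generated colored polyline drawings; only their low-level
statistics matter downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ApertureGrid",
    "ScrambleSpec",
    "OrientationSpectrum",
    "make_aperture_grid",
    "mask_image",
    "draw_angles",
    "scramble_image",
    "rms_contrast",
    "orientation_power",
    "generate_object_image",
    "luminance",
    "images_per_block",
    "DEFAULT_IMAGE_SIZE",
]

DEFAULT_IMAGE_SIZE = 512          # pixels across the +/- subtense field
MEAN_GRAY = 0.5


@dataclass
class ApertureGrid:
    """Hexagonally packed circular apertures inside a square field."""

    centers_deg: np.ndarray           # (n, 2)
    diameter_deg: float = 2.0
    gap_deg: float = 0.8
    subtense_deg: float = 7.6
    image_size_px: int = DEFAULT_IMAGE_SIZE

    @property
    def spacing_deg(self) -> float:
        return self.diameter_deg + self.gap_deg

    @property
    def px_per_deg(self) -> float:
        return self.image_size_px / (2.0 * self.subtense_deg)

    def centers_px(self) -> np.ndarray:
        """(n, 2) pixel (row, col) coordinates of aperture centres."""
        c = np.asarray(self.centers_deg)
        half = self.image_size_px / 2.0
        cols = half + c[:, 0] * self.px_per_deg
        rows = half - c[:, 1] * self.px_per_deg
        return np.column_stack([rows, cols])

    @property
    def radius_px(self) -> float:
        return self.diameter_deg / 2.0 * self.px_per_deg

    def aperture_mask(self) -> np.ndarray:
        """Boolean (size, size): True inside any aperture."""
        size = self.image_size_px
        rr, cc = np.mgrid[0:size, 0:size]
        mask = np.zeros((size, size), dtype=bool)
        for (r0, c0) in self.centers_px():
            mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius_px ** 2
        return mask


def make_aperture_grid(diameter_deg: float = 2.0, gap_deg: float = 0.8,
                       subtense_deg: float = 7.6,
                       image_size_px: int = DEFAULT_IMAGE_SIZE
                       ) -> ApertureGrid:
    """Hexagonal lattice of apertures fully contained in the square field.

    Centre spacing is diameter + gap; rows are spacing * sqrt(3)/2 apart
    with alternate rows offset by half a spacing.
    """
    if diameter_deg <= 0:
        raise ValueError("aperture diameter must be positive")
    if gap_deg < 0:
        raise ValueError("gap must be >= 0")
    if diameter_deg > 2 * subtense_deg:
        raise ValueError("aperture diameter exceeds the field subtense")
    s = diameter_deg + gap_deg
    dy = s * math.sqrt(3.0) / 2.0
    r = diameter_deg / 2.0
    limit = subtense_deg - r
    centers = []
    j = -int(math.ceil(2 * subtense_deg / dy))
    while j * dy <= subtense_deg:
        y = j * dy
        x0 = (s / 2.0) if (j % 2) else 0.0
        i = -int(math.ceil(2 * subtense_deg / s)) - 1
        while i * s + x0 <= subtense_deg:
            x = i * s + x0
            if abs(x) <= limit + 1e-12 and abs(y) <= limit + 1e-12:
                centers.append((x, y))
            i += 1
        j += 1
    return ApertureGrid(centers_deg=np.asarray(centers),
                        diameter_deg=diameter_deg, gap_deg=gap_deg,
                        subtense_deg=subtense_deg,
                        image_size_px=image_size_px)


def mask_image(image: np.ndarray, grid: ApertureGrid,
               background: float = MEAN_GRAY) -> np.ndarray:
    """Set pixels outside all apertures to mean gray (the occluder)."""
    out = np.array(image, dtype=float, copy=True)
    mask = grid.aperture_mask()
    if out.ndim == 3:
        out[~mask, :] = background
    else:
        out[~mask] = background
    return out


@dataclass
class ScrambleSpec:
    """Rotation-angle mixture: U[60, 120] or U[-120, -60], each w.p. 1/2."""

    low_deg: float = 60.0
    high_deg: float = 120.0
    seed: int = 0


def draw_angles(n: int, spec: ScrambleSpec = ScrambleSpec()) -> np.ndarray:
    """Draw n rotation angles from the scrambling mixture (degrees)."""
    rng = np.random.default_rng(spec.seed)
    sign = rng.choice([-1.0, 1.0], size=n)
    mag = rng.uniform(spec.low_deg, spec.high_deg, size=n)
    return sign * mag


def _rotate_patch(patch: np.ndarray, angle_deg: float,
                  circle: np.ndarray, center_rc: tuple,
                  background: float) -> np.ndarray:
    """Rotate a square patch about the exact (fractional) aperture centre
    and paste only inside the circular aperture: rotation maps the disk onto
    itself, so content never leaves the aperture, and whatever falls outside
    is clipped. The raw patch (not a masked copy) feeds the interpolation so
    boundary pixels blend with real neighbouring content."""
    a = math.radians(angle_deg)
    rot_mat = np.array([[math.cos(a), -math.sin(a)],
                        [math.sin(a), math.cos(a)]])
    c = np.asarray(center_rc)
    offset = c - rot_mat @ c
    if patch.ndim == 3:
        rot = np.stack([ndimage.affine_transform(
            patch[..., ch], rot_mat, offset=offset, order=1,
            mode="constant", cval=background)
            for ch in range(patch.shape[2])], axis=-1)
    else:
        rot = ndimage.affine_transform(patch, rot_mat, offset=offset,
                                       order=1, mode="constant",
                                       cval=background)
    out = patch.copy()
    if patch.ndim == 3:
        out[circle, :] = rot[circle, :]
    else:
        out[circle] = rot[circle]
    return out


def scramble_image(image: np.ndarray, grid: ApertureGrid,
                   spec: ScrambleSpec = ScrambleSpec(),
                   background: float = 1.0, content_tol: float = 0.02
                   ) -> tuple[np.ndarray, list]:
    """Rotate the content of every object-containing aperture.

    Each aperture whose circle contains pixels deviating from ``background``
    by more than ``content_tol`` is rotated about its centre by an
    independent draw from the angular mixture; empty apertures are left
    untouched. Deterministic for a fixed seed. Returns the scrambled image
    and the list of angles actually applied (one per rotated aperture).
    """
    out = np.array(image, dtype=float, copy=True)
    centers = grid.centers_px()
    r = grid.radius_px
    angles = draw_angles(len(centers), spec)
    applied = []
    size = image.shape[0]
    for (row0, col0), ang in zip(centers, angles):
        half = int(math.ceil(r)) + 2
        r0, r1 = int(round(row0)) - half, int(round(row0)) + half + 1
        c0, c1 = int(round(col0)) - half, int(round(col0)) + half + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, size), min(c1, size)
        patch = out[r0:r1, c0:c1]
        rr, cc = np.mgrid[r0:r1, c0:c1]
        circle = (rr - row0) ** 2 + (cc - col0) ** 2 <= r ** 2
        lum = patch.mean(axis=-1) if patch.ndim == 3 else patch
        if not np.any(np.abs(lum[circle] - background) > content_tol):
            continue
        out[r0:r1, c0:c1] = _rotate_patch(patch, ang, circle,
                                          (row0 - r0, col0 - c0), background)
        applied.append(float(ang))
    return out, applied


def rms_contrast(patch: np.ndarray) -> float:
    """RMS contrast: standard deviation of luminance over mean luminance."""
    p = np.asarray(patch, dtype=float)
    mean = float(p.mean())
    if abs(mean) < 1e-12:
        raise ValueError("zero-mean patch: RMS contrast undefined")
    return float(p.std() / mean)


@dataclass
class OrientationSpectrum:
    """Power in four 45-deg orientation bands of a vignetted patch."""

    bands: dict = field(default_factory=dict)   # name -> mean power
    patch_size: int = 45
    vignette_sigma_px: float = 8.0

    BAND_NAMES = ("horizontal", "oblique_45", "vertical", "oblique_135")

    @property
    def total(self) -> float:
        return float(sum(self.bands.values()))


def orientation_power(patch: np.ndarray, patch_size: int = 45,
                      vignette_sigma_px: float = 8.0) -> OrientationSpectrum:
    """Orientation-band power of a grayscale patch.

    The patch is multiplied by a centred Gaussian vignette (sigma = 8 px) to
    avoid edge artifacts, Fourier transformed, and the power spectrum is
    averaged within four 45-deg wedges centred on the horizontal, 45-deg,
    vertical and 135-deg stripe orientations (DC excluded). Band labels
    refer to the orientation of the image stripes, not of the frequency
    vector.
    """
    p = np.asarray(patch, dtype=float)
    if p.shape != (patch_size, patch_size):
        raise ValueError(f"expected a {patch_size}x{patch_size} patch, "
                         f"got {p.shape}")
    n = patch_size
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    vig = np.exp(-(((rr - c) ** 2 + (cc - c) ** 2)
                   / (2.0 * vignette_sigma_px ** 2)))
    # remove the mean before windowing: a DC pedestal times the vignette
    # would smear into genuine low-frequency power and dilute every band
    F = np.fft.fft2((p - p.mean()) * vig)
    power = np.abs(F) ** 2
    fy = np.fft.fftfreq(n)[:, None] * np.ones((1, n))
    fx = np.ones((n, 1)) * np.fft.fftfreq(n)[None, :]
    dc = (fx == 0) & (fy == 0)
    # stripe orientation is perpendicular to the frequency vector
    theta = np.mod(np.degrees(np.arctan2(fy, fx)) + 90.0, 180.0)
    bands = {}
    for i, name in enumerate(OrientationSpectrum.BAND_NAMES):
        center = 45.0 * i
        dist = np.abs((theta - center + 90.0) % 180.0 - 90.0)
        sel = (dist <= 22.5) & ~dc
        bands[name] = float(power[sel].mean())
    return OrientationSpectrum(bands=bands, patch_size=patch_size,
                               vignette_sigma_px=vignette_sigma_px)


def generate_object_image(seed: int = 0, size: int = DEFAULT_IMAGE_SIZE,
                          n_strokes: int = 12) -> np.ndarray:
    """Procedural colored line drawing on a white background, (size, size, 3).

    Strokes are random polylines with random dark colors and widths, lightly
    smoothed so that rotation/interpolation artefacts stay small, loosely
    emulating the spatial statistics of line drawings of common objects.
    """
    rng = np.random.default_rng(seed)
    img = np.ones((size, size, 3))
    center = size / 2.0
    spread = size * 0.3
    for _ in range(n_strokes):
        n_pts = rng.integers(3, 7)
        pts = rng.normal(center, spread, size=(n_pts, 2))
        pts = np.clip(pts, 2, size - 3)
        color = rng.uniform(0.0, 0.6, size=3)
        width = int(rng.integers(1, 4))
        for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
            npix = int(max(abs(y1 - y0), abs(x1 - x0))) * 2 + 1
            ys = np.linspace(y0, y1, npix).round().astype(int)
            xs = np.linspace(x0, x1, npix).round().astype(int)
            for dy in range(-width, width + 1):
                for dx in range(-width, width + 1):
                    yy = np.clip(ys + dy, 0, size - 1)
                    xx = np.clip(xs + dx, 0, size - 1)
                    img[yy, xx, :] = color
    for ch in range(3):
        img[..., ch] = ndimage.gaussian_filter(img[..., ch], 1.0)
    return img


def luminance(image: np.ndarray) -> np.ndarray:
    """Mean-of-channels luminance of an RGB image (grayscale passthrough)."""
    img = np.asarray(image, dtype=float)
    return img.mean(axis=-1) if img.ndim == 3 else img


def images_per_block(block_s: float = 16.0, image_duration_s: float = 0.25
                     ) -> int:
    """Number of stimulus presentations filling one block (e.g. 64 per 16 s)."""
    n = block_s / image_duration_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError("image duration does not evenly tile the block")
    return int(round(n))
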