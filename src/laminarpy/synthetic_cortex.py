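"""Parametric folded cortical-ribbon phantom.

Builds a matched pair of triangulated white-matter (WM) and pial (GM)
surfaces — the WM surface is a sinusoidal height field, the GM surface its
offset along local surface normals by a thickness field — then rasterises
the ribbon onto an isotropic voxel grid with ground-truth relative cortical
depth. Everything downstream (depth mapping, BOLD simulation, laminar
profiling) is validated against this phantom, so both the geometry and the
truth labels are exact by construction rather than segmented from images.

Coordinates are a right-handed world frame in millimetres; voxel indices are
0-based and a voxel's position is its centre; the grid is axis-aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
import nibabel as nib
import trimesh

__all__ = [
    "GeometryError",
    "Mesh",
    "SurfacePair",
    "PhantomConfig",
    "TissueVolume",
    "DepthTruth",
    "make_ribbon_phantom",
    "voxelize",
    "LABEL_OUTSIDE",
    "LABEL_WM",
    "LABEL_GM",
]

LABEL_OUTSIDE = 0
LABEL_WM = 1
LABEL_GM = 2


class GeometryError(ValueError):
    """Raised when a requested phantom geometry is not realisable."""


@dataclass
class Mesh:
    """Triangulated surface: vertices in mm, faces as vertex-index triples."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")

    def validate(self) -> None:
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")
        referenced = np.zeros(len(self.vertices), dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            raise ValueError("unreferenced vertices present")
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        if np.any(areas <= 0):
            raise ValueError("degenerate (zero-area) triangles present")

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    @property
    def face_count(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    def save_obj(self, path) -> None:
        self.to_trimesh().export(str(path))

    @classmethod
    def load_obj(cls, path) -> "Mesh":
        tm = trimesh.load(str(path), process=False, force="mesh")
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


@dataclass
class SurfacePair:
    """Matched WM/GM meshes: vertex i of ``wm`` corresponds to vertex i of ``gm``."""

    wm: Mesh
    gm: Mesh

    def validate(self) -> None:
        self.wm.validate()
        self.gm.validate()
        if self.wm.vertex_count != self.gm.vertex_count:
            raise ValueError("WM and GM vertex counts differ")
        if self.wm.face_count != self.gm.face_count:
            raise ValueError("WM and GM face counts differ")
        seg = self.gm.vertices - self.wm.vertices
        lengths = np.linalg.norm(seg, axis=1)
        if np.any(lengths <= 0):
            raise ValueError("zero-length WM->GM connecting segment")
        # Segments must leave the WM surface on its outward (GM) side.
        normals = self.wm.to_trimesh().vertex_normals
        if np.any(np.einsum("ij,ij->i", seg, normals) <= 0):
            raise ValueError("a connecting segment crosses the WM surface")

    @property
    def segments(self) -> np.ndarray:
        """(n, 2, 3): per matched vertex, WM endpoint then GM endpoint."""
        return np.stack([self.wm.vertices, self.gm.vertices], axis=1)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.gm.vertices - self.wm.vertices, axis=1)


ThicknessField = Union[float, Callable[[np.ndarray, np.ndarray], np.ndarray]]


@dataclass
class PhantomConfig:
    """Geometry of the synthetic ribbon.

    fov_mm            field of view per axis (x, y, z)
    voxel_size_mm     isotropic voxel edge (default 0.7, the acquisition grid)
    fold_amplitude_mm amplitude A of the sinusoidal fold (0 = flat slab)
    fold_wavelength_mm wavelength lambda of the fold
    thickness_mm      cortical thickness: scalar or callable f(x, y) -> mm
    mesh_edge_mm      edge length of the surface triangulation (default half a voxel)
    wm_level_mm       z of the WM mid-surface
    seed              reserved for randomised variants; geometry is deterministic
    """

    fov_mm: tuple = (20.0, 20.0, 8.0)
    voxel_size_mm: float = 0.7
    fold_amplitude_mm: float = 2.0
    fold_wavelength_mm: float = 20.0
    thickness_mm: ThicknessField = 2.5
    mesh_edge_mm: float = 0.35
    wm_level_mm: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.fold_amplitude_mm < 0:
            raise ValueError("fold amplitude must be >= 0")
        if self.fold_wavelength_mm <= 0:
            raise ValueError("fold wavelength must be positive")
        if not callable(self.thickness_mm) and self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")

    def thickness_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if callable(self.thickness_mm):
            t = np.asarray(self.thickness_mm(np.asarray(x), np.asarray(y)),
                           dtype=float)
        else:
            t = np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape,
                        float(self.thickness_mm))
        if np.any(t <= 0):
            raise ValueError("thickness field must be positive everywhere")
        return t

    def to_json(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items() if not callable(v)}
        d["fov_mm"] = list(self.fov_mm)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["fov_mm"] = tuple(d["fov_mm"])
        return cls(**d)


@dataclass
class TissueVolume:
    """Per-voxel tissue label grid (outside / WM / GM) with world geometry."""

    labels: np.ndarray          # (nx, ny, nz) int
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        # voxel (0,0,0) has its *centre* at origin + vs/2
        aff[:3, 3] = np.asarray(self.origin_mm) + self.voxel_size_mm / 2.0
        return aff

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) world coordinates of voxel centres."""
        idx = np.indices(self.labels.shape).astype(float)
        return (np.moveaxis(idx, 0, -1) + 0.5) * self.voxel_size_mm \
            + np.asarray(self.origin_mm)

    def save_nifti(self, path) -> None:
        nib.Nifti1Image(self.labels.astype(np.int16), self.affine).to_filename(str(path))


@dataclass
class DepthTruth:
    """Ground-truth depth and retinotopic tags on the same grid as the labels.

    ``rel_depth`` is NaN outside GM; 0 at the WM surface, 1 at the pial surface.
    Retinotopic tags emulate a coarse 3-eccentricity-band x 8-polar-wedge
    division of the visual field, assigned deterministically from (x, y).
    """

    rel_depth: np.ndarray       # (nx, ny, nz) float, NaN outside GM
    thickness: np.ndarray       # (nx, ny, nz) float, NaN outside GM
    ecc_band: np.ndarray        # (nx, ny, nz) int, -1 outside GM; bands 0,1,2
    polar_wedge: np.ndarray     # (nx, ny, nz) int, -1 outside GM; wedges 0..7
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        aff[:3, 3] = np.asarray(self.origin_mm) + self.voxel_size_mm / 2.0
        return aff

    def save_nifti(self, prefix) -> None:
        nib.Nifti1Image(self.rel_depth.astype(np.float32), self.affine) \
            .to_filename(f"{prefix}_reldepth.nii")
        nib.Nifti1Image(self.thickness.astype(np.float32), self.affine) \
            .to_filename(f"{prefix}_thickness.nii")


def _height(x, y, cfg: PhantomConfig):
    if cfg.fold_amplitude_mm == 0:
        return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape,
                       cfg.wm_level_mm)
    k = 2.0 * np.pi / cfg.fold_wavelength_mm
    return cfg.wm_level_mm + cfg.fold_amplitude_mm * np.sin(k * x) * np.sin(k * y)


def _height_grad(x, y, cfg: PhantomConfig):
    """(h_x, h_y) analytic partial derivatives of the WM height field."""
    if cfg.fold_amplitude_mm == 0:
        z = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
        return z, z.copy()
    k = 2.0 * np.pi / cfg.fold_wavelength_mm
    a = cfg.fold_amplitude_mm
    return (a * k * np.cos(k * x) * np.sin(k * y),
            a * k * np.sin(k * x) * np.cos(k * y))


def _unit_normal(x, y, cfg: PhantomConfig) -> np.ndarray:
    hx, hy = _height_grad(x, y, cfg)
    n = np.stack([-hx, -hy, np.ones_like(hx)], axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def _max_abs_curvature(cfg: PhantomConfig, n_samples: int = 121) -> float:
    """Max |principal curvature| of the WM height field, sampled on a grid."""
    if cfg.fold_amplitude_mm == 0:
        return 0.0
    k = 2.0 * np.pi / cfg.fold_wavelength_mm
    a = cfg.fold_amplitude_mm
    xs = np.linspace(0, cfg.fov_mm[0], n_samples)
    ys = np.linspace(0, cfg.fov_mm[1], n_samples)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    hx, hy = _height_grad(X, Y, cfg)
    hxx = -a * k * k * np.sin(k * X) * np.sin(k * Y)
    hyy = hxx
    hxy = a * k * k * np.cos(k * X) * np.cos(k * Y)
    # shape operator eigenvalues of a Monge patch
    w = np.sqrt(1 + hx ** 2 + hy ** 2)
    E = 1 + hx ** 2
    F = hx * hy
    G = 1 + hy ** 2
    L, M, N = hxx / w, hxy / w, hyy / w
    det_I = E * G - F * F
    K = (L * N - M * M) / det_I
    H = (E * N - 2 * F * M + G * L) / (2 * det_I)
    disc = np.sqrt(np.maximum(H * H - K, 0.0))
    return float(np.max(np.maximum(np.abs(H + disc), np.abs(H - disc))))


def make_ribbon_phantom(config: PhantomConfig) -> SurfacePair:
    """Build the matched WM/GM surface pair for ``config``.

    The WM surface is z = A sin(2 pi x / lambda) sin(2 pi y / lambda) over a
    regular grid; the GM surface displaces each WM vertex along the local WM
    normal by the thickness field. Rejects geometries where the offset
    surface would self-intersect (thickness x max curvature >= 1).
    """
    nx = max(int(round(config.fov_mm[0] / config.mesh_edge_mm)), 1)
    ny = max(int(round(config.fov_mm[1] / config.mesh_edge_mm)), 1)
    xs = np.linspace(0, config.fov_mm[0], nx + 1)
    ys = np.linspace(0, config.fov_mm[1], ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = _height(X, Y, config)
    wm_vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    thickness = config.thickness_at(X.ravel(), Y.ravel())
    kappa = _max_abs_curvature(config)
    if kappa * float(np.max(thickness)) >= 1.0:
        raise GeometryError(
            f"thickness {float(np.max(thickness)):.2f} mm exceeds the offset "
            f"limit 1/max|curvature| = {1.0 / kappa:.2f} mm; the GM surface "
            "would self-intersect")

    normals = _unit_normal(X.ravel(), Y.ravel(), config)
    gm_vertices = wm_vertices + thickness[:, None] * normals

    # two triangles per grid cell, shared topology for both surfaces
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    v00 = (ii * (ny + 1) + jj).ravel()
    v10 = ((ii + 1) * (ny + 1) + jj).ravel()
    v01 = (ii * (ny + 1) + jj + 1).ravel()
    v11 = ((ii + 1) * (ny + 1) + jj + 1).ravel()
    faces = np.concatenate([
        np.column_stack([v00, v10, v11]),
        np.column_stack([v00, v11, v01]),
    ])

    pair = SurfacePair(Mesh(wm_vertices, faces), Mesh(gm_vertices, faces.copy()))
    pair.validate()
    return pair


def _foot_points(points: np.ndarray, cfg: PhantomConfig,
                 n_iter: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on the WM height field for each query point.

    Newton iteration on (u, v) minimising |p - S(u, v)|^2 with
    S(u, v) = (u, v, h(u, v)). Returns (foot_uv, signed_distance) where the
    sign is positive on the GM side (along the upward normal).
    """
    p = np.asarray(points, dtype=float)
    u = p[:, 0].copy()
    v = p[:, 1].copy()
    k = 2.0 * np.pi / cfg.fold_wavelength_mm
    a = cfg.fold_amplitude_mm
    for _ in range(n_iter):
        if a == 0:
            break
        h = _height(u, v, cfg)
        hu, hv = _height_grad(u, v, cfg)
        huu = -a * k * k * np.sin(k * u) * np.sin(k * v)
        hvv = huu
        huv = a * k * k * np.cos(k * u) * np.cos(k * v)
        du = p[:, 0] - u
        dv = p[:, 1] - v
        dz = p[:, 2] - h
        # gradient of 0.5*|p - S|^2 wrt (u, v)
        g1 = -(du + dz * hu)
        g2 = -(dv + dz * hv)
        # Hessian (full Newton; Gauss-Newton fallback where not SPD)
        h11 = 1 + hu * hu - dz * huu
        h22 = 1 + hv * hv - dz * hvv
        h12 = hu * hv - dz * huv
        det = h11 * h22 - h12 * h12
        bad = (det <= 1e-12) | (h11 <= 0)
        h11 = np.where(bad, 1 + hu * hu, h11)
        h22 = np.where(bad, 1 + hv * hv, h22)
        h12 = np.where(bad, hu * hv, h12)
        det = h11 * h22 - h12 * h12
        step_u = (h22 * g1 - h12 * g2) / det
        step_v = (h11 * g2 - h12 * g1) / det
        u -= step_u
        v -= step_v
        if max(np.max(np.abs(step_u)), np.max(np.abs(step_v))) < 1e-12:
            break
    foot = np.column_stack([u, v, _height(u, v, cfg)])
    n = _unit_normal(u, v, cfg)
    signed = np.einsum("ij,ij->i", p - foot, n)
    return foot, signed


def voxelize(pair: SurfacePair,
             config: PhantomConfig) -> tuple[TissueVolume, DepthTruth]:
    """Classify every voxel centre and attach ground-truth depth.

    A centre at signed distance s from the WM surface (along the local
    normal, via the exact foot point of the analytic height field) is WM for
    s < 0, GM for 0 <= s <= thickness, outside beyond. GM voxels get true
    relative depth s / thickness and a deterministic retinotopic tag from
    their (x, y) position.
    """
    shape = tuple(max(int(round(f / config.voxel_size_mm)), 1)
                  for f in config.fov_mm)
    vol = TissueVolume(np.zeros(shape, dtype=np.int16), config.voxel_size_mm)

    # The WM footprint and the full z extent must lie inside the grid (one
    # voxel of tolerance for FOV rounding); GM may overhang in x/y where
    # normal offsets lean past the border — those vertices sit outside the
    # analysed volume and are simply never sampled.
    lo = pair.wm.vertices.min(axis=0)
    hi_wm = pair.wm.vertices.max(axis=0)
    z_hi = max(pair.wm.vertices[:, 2].max(), pair.gm.vertices[:, 2].max())
    grid_hi = np.asarray(shape) * config.voxel_size_mm
    tol = config.voxel_size_mm
    if np.any(lo < -tol) or np.any(hi_wm[:2] > grid_hi[:2] + tol) \
            or z_hi > grid_hi[2] + tol:
        raise ValueError(
            f"voxel grid extent {grid_hi} mm does not cover the surfaces "
            f"(WM bounds {lo} .. {hi_wm} mm, max z {z_hi:.2f} mm)")

    centers = vol.voxel_centers().reshape(-1, 3)
    foot, signed = _foot_points(centers, config)
    thickness = config.thickness_at(foot[:, 0], foot[:, 1])

    # the ribbon exists only where the surfaces are meshed: feet beyond the
    # meshed x/y extent (grid rounding slack) stay WM/outside
    inside_xy = ((foot[:, 0] >= 0) & (foot[:, 0] <= config.fov_mm[0])
                 & (foot[:, 1] >= 0) & (foot[:, 1] <= config.fov_mm[1]))
    labels = np.full(len(centers), LABEL_OUTSIDE, dtype=np.int16)
    labels[signed < 0] = LABEL_WM
    gm = (signed >= 0) & (signed <= thickness) & inside_xy
    labels[gm] = LABEL_GM
    vol.labels = labels.reshape(shape)

    rel = np.full(len(centers), np.nan)
    rel[gm] = np.clip(signed[gm] / thickness[gm], 0.0, 1.0)
    thick = np.full(len(centers), np.nan)
    thick[gm] = thickness[gm]

    # retinotopy: fovea at the (x, y) field-of-view centre; eccentricity
    # scaled so the farthest corner maps to 9 deg; 8 equal polar wedges
    cx, cy = config.fov_mm[0] / 2.0, config.fov_mm[1] / 2.0
    dx = centers[:, 0] - cx
    dy = centers[:, 1] - cy
    r = np.hypot(dx, dy)
    r_max = np.hypot(cx, cy)
    ecc_deg = 9.0 * r / r_max
    band = np.full(len(centers), -1, dtype=np.int16)
    band[gm] = np.minimum((ecc_deg[gm] // 3.0).astype(np.int16), 2)
    wedge = np.full(len(centers), -1, dtype=np.int16)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    wedge[gm] = np.minimum((theta[gm] / (2 * np.pi) * 8).astype(np.int16), 7)

    truth = DepthTruth(
        rel_depth=rel.reshape(shape),
        thickness=thick.reshape(shape),
        ecc_band=band.reshape(shape),
        polar_wedge=wedge.reshape(shape),
        voxel_size_mm=config.voxel_size_mm,
    )
    return vol, truth
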