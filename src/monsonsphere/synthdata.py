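"""Synthetic dentitions, cohorts, and toy dental meshes.

Real intraoral scans are not redistributable, so every stage of the
pipeline is exercised on generated data with the statistical structure
the analysis assumes:

* **Landmark sets** — 26 cusp tips at a fixed, bilaterally symmetric
  arch footprint on a spherical cap (the ``arch35`` layout: intercanine
  width 35 mm, canine-to-second-molar depth ≈ 62 mm, cap half-angle
  ≈ 33°), projected exactly onto a ground-truth sphere and perturbed by
  isotropic Gaussian noise.
* **Cohorts** — per-subject radii drawn from sex-specific normal
  distributions truncated at zero.  The default parameterization is the
  observed cohort: 32 males at 83.57 ± 13.12 mm and 32 females at
  71.13 ± 10.59 mm.
* **Meshes** — a low base band plus one smooth convex bump per landmark
  whose apex sits exactly at the noiseless landmark, as a fixture for
  cusp-tip detection.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landmarks import LABEL_CODES, LandmarkSet, from_array
from .groupstats import CohortRecord

__all__ = [
    "SyntheticTruth",
    "CohortSpec",
    "ARCH35_FOOTPRINT",
    "generate_landmarks",
    "generate_cohort",
    "generate_dentition_mesh",
    "arch_layout_points",
    "LayoutError",
]


class LayoutError(ValueError):
    """Unknown arch layout name."""


# Occlusal-plane footprint (x, y) in mm of the 13 right-side landmarks at
# the reference radius, anterior +y, buccal outward; the left side is the
# x-mirror.  Order matches Pt1..Pt13: canine tip, PM1 buccal/lingual,
# PM2 buccal/lingual, M1 MB/ML/DB/DL, M2 MB/ML/DB/DL.
_ARCH35_RIGHT: tuple[tuple[float, float], ...] = (
    (17.5, 36.0),  # canine tip
    (24.0, 27.0),  # PM1 buccal
    (18.0, 25.0),  # PM1 lingual
    (27.0, 17.0),  # PM2 buccal
    (20.0, 15.0),  # PM2 lingual
    (30.0, 6.0),   # M1 mesio-buccal
    (22.0, 5.0),   # M1 mesio-lingual
    (31.0, -4.0),  # M1 disto-buccal
    (23.0, -5.0),  # M1 disto-lingual
    (32.0, -15.0), # M2 mesio-buccal
    (24.0, -16.0), # M2 mesio-lingual
    (32.0, -25.0), # M2 disto-buccal
    (24.0, -26.0), # M2 disto-lingual
)

ARCH35_FOOTPRINT: np.ndarray = np.array(
    list(_ARCH35_RIGHT) + [(-x, y) for x, y in _ARCH35_RIGHT], float
)
ARCH35_FOOTPRINT -= ARCH35_FOOTPRINT.mean(axis=0)
ARCH35_FOOTPRINT.setflags(write=False)

#: Reference radius at which the footprint's absolute distances apply.
_REFERENCE_RADIUS = 77.35

_LAYOUTS = {"arch35": ARCH35_FOOTPRINT}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth sphere and noise settings for a generated dentition."""

    center: tuple[float, float, float] = (0.0, 0.0, 100.0)
    radius: float = _REFERENCE_RADIUS  # mm
    noise_sd: float = 0.1  # mm, isotropic Gaussian per coordinate
    seed: int = 0
    layout: str = "arch35"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Sex-specific normal radius distributions; defaults are the
    observed 32+32 cohort parameters."""

    n_male: int = 32
    n_female: int = 32
    mean_male: float = 83.57
    sd_male: float = 13.12
    mean_female: float = 71.13
    sd_female: float = 10.59
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.sd_male < 0 or self.sd_female < 0:
            raise ValueError("SDs must be non-negative")


def arch_layout_points(
    layout: str, radius: float, center: Sequence[float]
) -> np.ndarray:
    """Noiseless landmark positions: the layout footprint scaled with the
    sphere, lifted exactly onto the sphere's lower cap.

    The footprint is defined at the reference radius and scales
    proportionally with ``radius`` so the cap angles (not the absolute
    arch size) are what the layout fixes.
    """
    if layout not in _LAYOUTS:
        raise LayoutError(
            f"unknown layout {layout!r}; available: {sorted(_LAYOUTS)}"
        )
    fp = _LAYOUTS[layout] * (radius / _REFERENCE_RADIUS)
    c = np.asarray(center, float)
    sag = np.sqrt(radius**2 - np.einsum("ij,ij->i", fp, fp))
    pts = np.column_stack([c[0] + fp[:, 0], c[1] + fp[:, 1], c[2] - sag])
    return pts


def generate_landmarks(truth: SyntheticTruth) -> tuple[LandmarkSet, SyntheticTruth]:
    """Generate one noisy 26-point dentition from its ground truth.

    Deterministic given ``(layout, seed)``: the same truth always yields
    bitwise-identical coordinates.
    """
    pts = arch_layout_points(truth.layout, truth.radius, truth.center)
    rng = np.random.default_rng(truth.seed)
    if truth.noise_sd > 0:
        pts = pts + rng.normal(0.0, truth.noise_sd, pts.shape)
    lms = from_array(pts, subject_id=f"synthetic-{truth.seed}", codes=LABEL_CODES)
    return lms, truth


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Draw a cohort of per-subject radii from the sex-specific normals.

    Draws are truncated at zero by resampling (practically never
    triggered at the default parameters, where zero is ~6 SDs below the
    female mean).  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)

    def draw(n: int, mean: float, sd: float) -> np.ndarray:
        vals = rng.normal(mean, sd, n)
        while np.any(vals <= 0):
            bad = vals <= 0
            vals[bad] = rng.normal(mean, sd, int(bad.sum()))
        return vals

    males = draw(spec.n_male, spec.mean_male, spec.sd_male)
    females = draw(spec.n_female, spec.mean_female, spec.sd_female)
    records = [
        CohortRecord(f"M{i + 1:03d}", "M", float(v)) for i, v in enumerate(males)
    ] + [
        CohortRecord(f"F{i + 1:03d}", "F", float(v)) for i, v in enumerate(females)
    ]
    return records


def _bump_profile(r: np.ndarray, bump_radius: float, height: float) -> np.ndarray:
    """Smooth convex bump: cosine cap, zero outside bump_radius, apex at
    exactly `height`."""
    z = np.zeros_like(r)
    inside = r < bump_radius
    z[inside] = height * 0.5 * (1.0 + np.cos(np.pi * r[inside] / bump_radius))
    return z


def generate_dentition_mesh(
    truth: SyntheticTruth,
    cusp_height: float = 3.0,
    bump_radius: float = 1.6,
    grid_step: float = 0.35,
):
    """Build a triangulated toy dentition surface plus its true apices.

    A flat rectangular base band under the arch footprint carries one
    cosine-profile bump per landmark; each bump's apex lies exactly at
    the noiseless landmark position, so the mesh is an exact fixture for
    cusp-tip detection.  Returns ``(trimesh.Trimesh, apices (26, 3))``.
    """
    import trimesh

    if cusp_height <= 0:
        raise ValueError("cusp_height must be positive")
    apices = arch_layout_points(truth.layout, truth.radius, truth.center)

    pad = bump_radius + 2.0
    x0, x1 = apices[:, 0].min() - pad, apices[:, 0].max() + pad
    y0, y1 = apices[:, 1].min() - pad, apices[:, 1].max() + pad
    xs = np.arange(x0, x1 + grid_step, grid_step)
    ys = np.arange(y0, y1 + grid_step, grid_step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    base_z = apices[:, 2].min() - cusp_height
    gz = np.full(gx.shape, base_z)
    # Snap the nearest grid node under each apex to the apex (x, y) so the
    # apex is a mesh vertex exactly; then add each bump in its footprint.
    ix = np.clip(np.round((apices[:, 0] - x0) / grid_step).astype(int), 0, len(xs) - 1)
    iy = np.clip(np.round((apices[:, 1] - y0) / grid_step).astype(int), 0, len(ys) - 1)
    gx = gx.copy()
    gy = gy.copy()
    gx[ix, iy] = apices[:, 0]
    gy[ix, iy] = apices[:, 1]
    for k, (ax, ay, az) in enumerate(apices):
        r = np.hypot(gx - ax, gy - ay)
        bump = _bump_profile(r, bump_radius, az - base_z)
        gz = np.maximum(gz, base_z + bump)

    nx, ny = gx.shape
    vertices = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
    )
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    return mesh, apices
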