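"""Synthetic multi-channel nucleus images with analytic ground truth.

Renders microscopy-like fields of a single cardiomyocyte nucleus:

* ``chromatin`` — an ellipsoidal nucleus, optionally with a chromatin
  protrusion spilling past one tip (a disk placed across the boundary);
* ``tubulin``  — uniform cytoplasmic signal plus a perinuclear ring
  ("MT cage") of tunable enrichment, optionally boosted at the tips;
* ``foci``     — punctate reporter foci at given positions;
* ``lamina``   — a thin shell at the nuclear boundary, with a gap over the
  protrusion (partial lamina coverage).

Ground truth (shape, protrusion area, enrichment, foci) is recorded before
point-spread blur and noise are applied.  All randomness flows through the
seed in the spec, so identical specs render byte-identical images.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from ._util import rng_from
from .errors import GeometryError

CHANNEL_ORDER = ("chromatin", "tubulin", "foci", "lamina")


@dataclass
class Protrusion:
    present: bool = False
    tip_sign: int = 1
    radius: float = 0.8              # um
    offset: float = 1.0              # um beyond (tip - radius)
    lamina_coverage_fraction: float = 0.5


@dataclass
class Tubulin:
    cytoplasm_level: float = 1.0
    enrichment_factor: float = 2.2   # ring level / cytoplasm level
    ring_width: float = 1.0          # um
    tip_boost: float = 0.0           # extra fractional enrichment at tips


@dataclass
class Focus:
    center: tuple                    # um, nucleus frame (x along major axis)
    radius: float = 0.25             # um
    level: float = 1.0


@dataclass
class ImageSpec:
    """Geometry, optics and noise of one rendered nucleus field."""

    dimensionality: int = 2
    voxel_size: float = 0.1                         # um (0.25 typical in 3-D)
    grid_shape: tuple | None = None                 # rows(y) x cols(x) [x planes]
    nucleus_semi_axes: tuple = (6.2, 2.8)           # um; (a, b[, c]), a = major
    orientation: float = 0.0                        # radians, in-plane
    chromatin_level: float = 1.0
    background_level: float = 0.02
    lamina_shell: dict = field(default_factory=lambda: {"thickness": 0.2, "level": 1.0})
    protrusion: Protrusion = field(default_factory=Protrusion)
    tubulin: Tubulin = field(default_factory=Tubulin)
    foci: list = field(default_factory=list)
    foci_background: float = 0.05
    psf_sigma: float = 0.1                          # um
    noise: dict = field(default_factory=lambda: {"model": "gaussian", "sd": 0.0})
    seed: int = 0
    margin: float = 6.5                             # um of cytoplasm around nucleus

    def validate(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        axes = self.nucleus_semi_axes
        if len(axes) < 2 or any(a <= 0 for a in axes):
            raise ValueError("nucleus_semi_axes must be positive")
        if self.tubulin.ring_width <= 0:
            raise ValueError("tubulin ring_width must be positive")
        if self.tubulin.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")
        if self.noise.get("sd", 0.0) < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class GroundTruth:
    """Analytic per-image truth, recorded before blur and noise."""

    nuclear_length: float            # um, 2a
    nuclear_width: float             # um, 2b
    aspect_ratio: float
    area: float                      # um^2 (2-D) — pi a b
    volume: float                    # um^3 (3-D, 0 in 2-D)
    protrusion_present: bool
    protrusion_area: float           # um^2 outside the nuclear ellipse
    enrichment_factor: float
    foci_count: int
    foci_centers: list

    def to_dict(self):
        return asdict(self)


def _default_grid_shape(spec: ImageSpec):
    a, b = spec.nucleus_semi_axes[:2]
    c, s = abs(np.cos(spec.orientation)), abs(np.sin(spec.orientation))
    half_x = np.hypot(a * c, b * s) + spec.margin
    half_y = np.hypot(a * s, b * c) + spec.margin
    ny = 2 * int(np.ceil(half_y / spec.voxel_size)) + 1
    nx = 2 * int(np.ceil(half_x / spec.voxel_size)) + 1
    if spec.dimensionality == 3:
        cz = spec.nucleus_semi_axes[2] if len(spec.nucleus_semi_axes) > 2 else b
        nz = 2 * int(np.ceil((cz + 2.5) / spec.voxel_size)) + 1
        return (nz, ny, nx)
    return (ny, nx)


def _nucleus_frame_coords(spec: ImageSpec, shape):
    """Physical coordinates (um) in the nucleus frame, origin at grid centre."""
    vs = spec.voxel_size
    if spec.dimensionality == 2:
        ny, nx = shape
        y = (np.arange(ny) - (ny - 1) / 2) * vs
        x = (np.arange(nx) - (nx - 1) / 2) * vs
        Y, X = np.meshgrid(y, x, indexing="ij")
        ct, st = np.cos(spec.orientation), np.sin(spec.orientation)
        U = X * ct + Y * st
        V = -X * st + Y * ct
        return U, V, None
    nz, ny, nx = shape
    z = (np.arange(nz) - (nz - 1) / 2) * vs
    y = (np.arange(ny) - (ny - 1) / 2) * vs
    x = (np.arange(nx) - (nx - 1) / 2) * vs
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    ct, st = np.cos(spec.orientation), np.sin(spec.orientation)
    U = X * ct + Y * st
    V = -X * st + Y * ct
    return U, V, Z


def protrusion_outside_area(spec: ImageSpec) -> float:
    """Area (um^2) of the protrusion disk lying outside the nuclear ellipse.

    Exact geometric quadrature on a fine sub-grid independent of the image
    raster (the unblurred rendered mask is the cross-check, not the source).
    """
    p = spec.protrusion
    if not p.present:
        return 0.0
    a, b = spec.nucleus_semi_axes[:2]
    cx = p.tip_sign * (a - p.radius + p.offset)
    n = 801
    g = np.linspace(-p.radius, p.radius, n)
    dx = g[1] - g[0]
    GU, GV = np.meshgrid(g + cx, g, indexing="ij")
    in_disk = (GU - cx) ** 2 + GV ** 2 <= p.radius ** 2
    outside = (GU / a) ** 2 + (GV / b) ** 2 > 1.0
    return float(np.sum(in_disk & outside) * dx * dx)


def generate_nucleus_image(spec: ImageSpec):
    """Render the channels and return ``(channels dict, GroundTruth)``.

    Channels are float arrays in arbitrary intensity units, blurred by an
    isotropic Gaussian PSF and degraded by the configured noise model.
    """
    spec.validate()
    shape = spec.grid_shape or _default_grid_shape(spec)
    axes = spec.nucleus_semi_axes
    a, b = axes[:2]
    U, V, Z = _nucleus_frame_coords(spec, shape)

    if spec.dimensionality == 2:
        m2 = (U / a) ** 2 + (V / b) ** 2
        half_extents = ((np.hypot(a * np.cos(spec.orientation), b * np.sin(spec.orientation))),
                        (np.hypot(a * np.sin(spec.orientation), b * np.cos(spec.orientation))))
        field_half = ((shape[1] - 1) / 2 * spec.voxel_size,
                      (shape[0] - 1) / 2 * spec.voxel_size)
        if field_half[0] - half_extents[0] < 2.0 or field_half[1] - half_extents[1] < 2.0:
            raise GeometryError("nucleus does not fit in the grid with a 2 um margin")
    else:
        cz = axes[2] if len(axes) > 2 else b
        m2 = (U / a) ** 2 + (V / b) ** 2 + (Z / cz) ** 2
        field_half_z = (shape[0] - 1) / 2 * spec.voxel_size
        if field_half_z - cz < 1.0:
            raise GeometryError("nucleus does not fit in the grid axially")

    nucleus = m2 <= 1.0
    vs = spec.voxel_size
    dist_out = ndimage.distance_transform_edt(~nucleus) * vs
    dist_in = ndimage.distance_transform_edt(nucleus) * vs

    # --- chromatin ---------------------------------------------------------
    chromatin = np.full(shape, spec.background_level * spec.chromatin_level)
    chromatin[nucleus] = spec.chromatin_level
    p = spec.protrusion
    if p.present:
        cx = p.tip_sign * (a - p.radius + p.offset)
        if spec.dimensionality == 2:
            disk = (U - cx) ** 2 + V ** 2 <= p.radius ** 2
        else:
            disk = (U - cx) ** 2 + V ** 2 + Z ** 2 <= p.radius ** 2
        chromatin[disk] = spec.chromatin_level

    # --- tubulin -----------------------------------------------------------
    tub = spec.tubulin
    cyt = tub.cytoplasm_level
    tubulin = np.full(shape, cyt)
    ring = (~nucleus) & (dist_out <= tub.ring_width)
    level = tub.enrichment_factor
    if tub.tip_boost > 0:
        ang = np.arctan2(np.abs(V), np.abs(U))
        tipness = np.clip(1.0 - ang / (np.pi / 6), 0.0, 1.0)
        tubulin[ring] = cyt * level * (1.0 + tub.tip_boost * tipness[ring])
    else:
        tubulin[ring] = cyt * level

    # --- lamina ------------------------------------------------------------
    lam = spec.lamina_shell
    shell = (dist_out <= lam["thickness"] / 2) & (dist_in <= lam["thickness"] / 2) \
        | ((dist_out > 0) & (dist_out <= lam["thickness"] / 2)) \
        | ((dist_in > 0) & (dist_in <= lam["thickness"] / 2))
    lamina = np.zeros(shape)
    lamina[shell] = lam["level"]
    if p.present and p.lamina_coverage_fraction < 1.0:
        # open a gap over the protrusion arc proportional to uncovered fraction
        half_span = np.arcsin(min(p.radius / max(a, 1e-6), 1.0))
        gap = half_span * (1.0 - p.lamina_coverage_fraction)
        ang_tip = np.arctan2(V, p.tip_sign * U)
        lamina[shell & (np.abs(ang_tip) < gap)] = 0.0

    # --- foci --------------------------------------------------------------
    foci_img = np.full(shape, spec.foci_background)
    for f in spec.foci:
        f = f if isinstance(f, Focus) else Focus(**f)
        fx, fy = f.center[0], f.center[1]
        if spec.dimensionality == 2:
            blob = (U - fx) ** 2 + (V - fy) ** 2 <= f.radius ** 2
        else:
            fz = f.center[2] if len(f.center) > 2 else 0.0
            blob = (U - fx) ** 2 + (V - fy) ** 2 + (Z - fz) ** 2 <= f.radius ** 2
        foci_img[blob] = f.level

    truth = GroundTruth(
        nuclear_length=2 * a, nuclear_width=2 * b, aspect_ratio=a / b,
        area=float(np.pi * a * b),
        volume=float(4 / 3 * np.pi * a * b * (axes[2] if len(axes) > 2 else b))
        if spec.dimensionality == 3 else 0.0,
        protrusion_present=bool(p.present),
        protrusion_area=protrusion_outside_area(spec),
        enrichment_factor=tub.enrichment_factor,
        foci_count=len(spec.foci),
        foci_centers=[list(map(float, (f["center"] if isinstance(f, dict)
                                       else f.center))) for f in spec.foci],
    )

    channels = {"chromatin": chromatin, "tubulin": tubulin,
                "foci": foci_img, "lamina": lamina}
    sigma_px = spec.psf_sigma / vs
    rng = rng_from(spec.seed, "image")
    sd = spec.noise.get("sd", 0.0)
    model = spec.noise.get("model", "gaussian")
    for name, img in channels.items():
        if sigma_px > 0:
            img = ndimage.gaussian_filter(img, sigma_px)
        if sd > 0:
            if model == "poisson-gaussian":
                gain = spec.noise.get("gain", 0.01)
                img = rng.poisson(np.clip(img, 0, None) / gain) * gain \
                    + rng.normal(0.0, sd, img.shape)
            else:
                img = img + rng.normal(0.0, sd, img.shape)
        channels[name] = img
    return channels, truth
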