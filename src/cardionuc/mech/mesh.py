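"""Axisymmetric body-fitted mesh of the resting cardiomyocyte quarter-domain.

The reference (stress-free) configuration is a cylinder of radius
``cell_radius`` and half-length ``cell_half_length`` containing a round
nucleus (radius ``nucleus_initial_radius``, split into nucleoplasm and a
thin envelope+lamina layer) surrounded by an ellipsoidal microtubule cage
elongated along the cell axis.  By symmetry only the quarter plane
(r >= 0, z >= 0) is meshed: rays fan out from the nucleus centre and
radial layers follow the material interfaces exactly, so the lamina is
resolved with two element layers through its thickness and every element
carries an unambiguous region label.

Regions: 0 = nucleoplasm, 1 = lamina (NE + lamina), 2 = MT cage,
3 = cytoplasm (myofibrils).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import GeometryError

REGION_NAMES = ("nucleoplasm", "lamina", "cage", "cytoplasm")
NUCLEOPLASM, LAMINA, CAGE, CYTOPLASM = range(4)


@dataclass
class MechGeometry:
    """Reference geometry (um)."""

    cell_radius: float = 9.0
    cell_half_length: float = 16.0
    nucleus_initial_radius: float = 3.5
    # outer cage ellipsoid: thin at the equator, thick at the poles — the
    # perinuclear MT cage is enriched at the nuclear tips
    cage_semi_axes: tuple = (4.2, 6.8)      # (radial, axial)
    lamina_thickness: float = 0.15
    mesh_target_edge: float = 0.25          # near the lamina; graded outward

    @property
    def cage_thickness(self) -> float:
        """Equatorial cage thickness implied by the outer ellipsoid."""
        return self.cage_semi_axes[0] - self.nucleus_initial_radius

    def validate(self) -> None:
        a = self.nucleus_initial_radius
        cr, cz = self.cage_semi_axes
        if not (cr > a and cz > a):
            raise GeometryError("cage ellipsoid must contain the nucleus")
        if not (cr < self.cell_radius and cz < self.cell_half_length):
            raise GeometryError("cage must lie inside the cell")
        if not self.lamina_thickness < a / 5:
            raise GeometryError("lamina_thickness must be < nucleus radius / 5")
        if self.lamina_thickness <= 0 or a <= 0:
            raise GeometryError("non-positive layer dimensions")


@dataclass
class Mesh:
    nodes: np.ndarray          # (N, 2) reference (r, z)
    elements: np.ndarray       # (E, 3) node indices, CCW
    region: np.ndarray         # (E,) region labels
    axis_nodes: np.ndarray     # r = 0
    midplane_nodes: np.ndarray  # z = 0 (symmetry plane)
    end_nodes: np.ndarray      # z = cell_half_length (fixed cell end)
    # landmark node indices on material interfaces
    nucleus_pole: int          # (0, a)
    nucleus_equator: int       # (a, 0)
    cage_pole: int             # (0, cz)
    cage_equator: int          # (cr, 0)

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.elements)


def _ellipse_radius(theta, ar, az):
    c, s = np.cos(theta), np.sin(theta)
    return 1.0 / np.sqrt((c / ar) ** 2 + (s / az) ** 2)


def _outer_radius(theta, R, L):
    c, s = np.cos(theta), np.sin(theta)
    with np.errstate(divide="ignore"):
        tr = np.where(c > 1e-12, R / np.maximum(c, 1e-12), np.inf)
        tz = np.where(s > 1e-12, L / np.maximum(s, 1e-12), np.inf)
    return np.minimum(tr, tz)


def build_mesh(geometry: MechGeometry, refine: float = 1.0) -> Mesh:
    """Structured ray-layer triangulation of the quarter-domain.

    ``refine`` scales both the angular and radial resolution (2.0 = twice
    as fine), used for mesh-convergence checks.
    """
    geometry.validate()
    g = geometry
    a = g.nucleus_initial_radius
    t_l = g.lamina_thickness
    cr, cz = g.cage_semi_axes

    n_theta = max(12, int(round(refine * (np.pi / 2 * a) / g.mesh_target_edge / 1.0)))
    theta = np.linspace(0.0, np.pi / 2, n_theta + 1)

    # radial stations along each ray, per region band
    n_nuc = max(4, int(round(refine * (a - t_l) / (2.5 * g.mesh_target_edge))))
    n_lam = 2 if refine < 2 else int(round(refine))
    n_cage = max(3, int(round(refine * 5)))
    n_cyt = max(6, int(round(refine * 10)))

    r_lam_in = a - t_l
    r_cage = _ellipse_radius(theta, cr, cz)
    r_out = _outer_radius(theta, g.cell_radius, g.cell_half_length)
    if np.any(r_cage >= r_out):
        raise GeometryError("cage touches the cell boundary")

    layers = []        # list of per-ray radii arrays, innermost first
    bands = []         # region label of the band *below* each ring
    # nucleoplasm rings (fan handled separately from the centre node)
    for j in range(1, n_nuc + 1):
        layers.append(np.full(n_theta + 1, r_lam_in * j / n_nuc))
        bands.append(NUCLEOPLASM)
    for j in range(1, n_lam + 1):
        layers.append(np.full(n_theta + 1, r_lam_in + t_l * j / n_lam))
        bands.append(LAMINA)
    for j in range(1, n_cage + 1):
        frac = j / n_cage
        layers.append(a + (r_cage - a) * frac)
        bands.append(CAGE)
    # cytoplasm: geometric grading away from the cage
    ratio = 1.35
    weights = np.cumsum(ratio ** np.arange(n_cyt))
    weights /= weights[-1]
    for j in range(n_cyt):
        layers.append(r_cage + (r_out - r_cage) * weights[j])
        bands.append(CYTOPLASM)

    n_rings = len(layers)
    ct, st = np.cos(theta), np.sin(theta)
    nodes = [np.array([0.0, 0.0])]
    ring_index = np.empty((n_rings, n_theta + 1), dtype=int)
    for jr in range(n_rings):
        for it in range(n_theta + 1):
            ring_index[jr, it] = len(nodes)
            t = layers[jr][it]
            nodes.append(np.array([t * ct[it], t * st[it]]))
    nodes = np.array(nodes)

    elements = []
    region = []
    # central fan
    for it in range(n_theta):
        elements.append([0, ring_index[0, it], ring_index[0, it + 1]])
        region.append(NUCLEOPLASM)
    # quad bands split along alternating diagonals for isotropy
    for jr in range(n_rings - 1):
        lab = bands[jr + 1]
        for it in range(n_theta):
            n00 = ring_index[jr, it]
            n01 = ring_index[jr, it + 1]
            n10 = ring_index[jr + 1, it]
            n11 = ring_index[jr + 1, it + 1]
            if (it + jr) % 2 == 0:
                elements.append([n00, n10, n11])
                elements.append([n00, n11, n01])
            else:
                elements.append([n00, n10, n01])
                elements.append([n10, n11, n01])
            region.extend([lab, lab])
    elements = np.array(elements, dtype=int)
    region = np.array(region, dtype=int)

    # fix orientation (positive area)
    p = nodes[elements]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) \
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    p = nodes[elements]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) \
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    if np.any(area2 <= 0):
        raise GeometryError("degenerate or inverted element in mesh")

    tol = 1e-9
    axis_nodes = np.flatnonzero(np.abs(nodes[:, 0]) < tol)
    midplane_nodes = np.flatnonzero(np.abs(nodes[:, 1]) < tol)
    end_nodes = np.flatnonzero(np.abs(nodes[:, 1] - g.cell_half_length) < 1e-6)

    lam_ring = n_nuc + n_lam - 1               # outer lamina ring index
    cage_ring = n_nuc + n_lam + n_cage - 1     # outer cage ring index
    return Mesh(
        nodes=nodes, elements=elements, region=region,
        axis_nodes=axis_nodes, midplane_nodes=midplane_nodes,
        end_nodes=end_nodes,
        nucleus_pole=int(ring_index[lam_ring, n_theta]),
        nucleus_equator=int(ring_index[lam_ring, 0]),
        cage_pole=int(ring_index[cage_ring, n_theta]),
        cage_equator=int(ring_index[cage_ring, 0]),
    )


def region_volumes(mesh: Mesh) -> dict:
    """Revolved (full 3-D) volume per region in the reference configuration.

    Exact for straight-edged triangles: V = 2*pi*r_centroid*A summed, times
    two for the mirrored half below the midplane.
    """
    p = mesh.nodes[mesh.elements]
    area = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    rc = p[:, :, 0].mean(axis=1)
    vol = 2.0 * 2.0 * np.pi * rc * area
    return {name: float(vol[mesh.region == i].sum())
            for i, name in enumerate(REGION_NAMES)}


def analytic_region_volumes(geometry: MechGeometry) -> dict:
    """Closed-form region volumes of the reference configuration."""
    g = geometry
    a = g.nucleus_initial_radius
    vn_in = 4 / 3 * np.pi * (a - g.lamina_thickness) ** 3
    vn = 4 / 3 * np.pi * a ** 3
    vcage_out = 4 / 3 * np.pi * g.cage_semi_axes[0] ** 2 * g.cage_semi_axes[1]
    vcell = np.pi * g.cell_radius ** 2 * (2 * g.cell_half_length)
    return {
        "nucleoplasm": vn_in,
        "lamina": vn - vn_in,
        "cage": vcage_out - vn,
        "cytoplasm": vcell - vcage_out,
    }
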