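"""Axisymmetric finite-strain FE solver with active stress.

Total Cauchy stress = passive compressible neo-Hookean stress + active
stress: the myofibril contractility tensor rho_ij in the cytoplasm
(isotropic with magnitude rho0 before polarization, concentrated along the
local maximum-principal-stress direction afterwards) and an isotropic
compressive stress of magnitude sigma_MT in the perinuclear MT cage.

Kinematics: linear (P1) triangles on the quarter-plane mesh with one-point
integration at the element centroid; the hoop stretch is (r + u_r)/r at the
centroid.  The weak form is total-Lagrangian, with the active Cauchy stress
mapped to first Piola-Kirchhoff via P_act = J sigma_act F^{-T}.  Newton
iterations use a finite-difference consistent tangent assembled per element
(vectorized over all elements), and load is applied in quasi-static ramp
increments with automatic step halving on non-convergence.

Boundary conditions: u_r = 0 on the axis, u_z = 0 on the symmetry midplane
and on the cell end face (the myocardial constraint that keeps cell length
constant); the lateral surface is traction-free.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..errors import SolverError
from .mesh import CAGE, CYTOPLASM, LAMINA, NUCLEOPLASM, Mesh, MechGeometry, build_mesh

REL_TOL = 1e-8
ABS_TOL = 1e-10
MAX_NEWTON = 40


@dataclass
class MechMaterials:
    """Young's moduli (kPa) and Poisson ratios per region.

    Defaults are the calibrated wild-type set: a compressible myofibrillar
    cytoplasm, a shear-soft but nearly incompressible nucleoplasm, the
    perinuclear MT cage, and a stiff NE+lamina layer (reduced to 10 kPa in
    the mutant-lamin scenarios).
    """

    moduli: dict = field(default_factory=lambda: {
        "cytoplasm": 7.0, "nucleoplasm": 0.3, "cage": 8.0, "lamina": 40.0})
    poisson: dict = field(default_factory=lambda: {
        "cytoplasm": 0.3, "nucleoplasm": 0.48, "cage": 0.4, "lamina": 0.3})

    def validate(self):
        for k, v in self.moduli.items():
            if v <= 0:
                raise ValueError(f"modulus for {k} must be positive")
        for k, v in self.poisson.items():
            if not -1 < v < 0.5:
                raise ValueError(f"poisson ratio for {k} out of range")

    def lame(self, region_names):
        mu = np.array([self.moduli[n] / (2 * (1 + self.poisson[n]))
                       for n in region_names])
        lam = np.array([self.moduli[n] * self.poisson[n]
                        / ((1 + self.poisson[n]) * (1 - 2 * self.poisson[n]))
                        for n in region_names])
        return mu, lam


@dataclass
class ActiveState:
    """Active loading: myofibril contractility and MT-cage compression."""

    rho0: float = 2.2            # kPa, isotropic contractility magnitude
    sigma_mt: float = 3.8        # kPa, cage compressive stress (>= 0)
    n_steps: int = 20            # quasi-static ramp increments from zero
    polarization: str = "single"  # "single" post-ramp update or "none"
    polarization_lambda: float = 0.5

    def validate(self):
        if self.sigma_mt < 0:
            raise ValueError("sigma_mt must be >= 0")
        if self.rho0 < 0:
            raise ValueError("rho0 must be >= 0")
        if not 0 <= self.polarization_lambda <= 1:
            raise ValueError("polarization_lambda in [0, 1]")
        if self.polarization not in ("single", "none"):
            raise ValueError("polarization must be 'single' or 'none'")


class Model:
    """Assembled mesh + materials + element quadrature data."""

    def __init__(self, geometry: MechGeometry, materials: MechMaterials,
                 active: ActiveState, refine: float = 1.0):
        materials.validate()
        active.validate()
        self.geometry = geometry
        self.materials = materials
        self.active = active
        self.mesh = build_mesh(geometry, refine=refine)
        m = self.mesh
        p = m.nodes[m.elements]                       # (E, 3, 2)
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        det = v1[:, 0] * v2[:, 1] - v2[:, 0] * v1[:, 1]
        self.area = 0.5 * det
        # shape-function gradients dN_a/d(R,Z), constant per element
        self.grads = np.empty((m.n_elements, 3, 2))
        self.grads[:, 1, 0] = v2[:, 1] / det
        self.grads[:, 1, 1] = -v2[:, 0] / det
        self.grads[:, 2, 0] = -v1[:, 1] / det
        self.grads[:, 2, 1] = v1[:, 0] / det
        self.grads[:, 0] = -self.grads[:, 1] - self.grads[:, 2]
        self.rc = p[:, :, 0].mean(axis=1)             # centroid radius > 0
        from .mesh import REGION_NAMES
        names = [REGION_NAMES[i] for i in m.region]
        self.mu, self.lam = materials.lame(names)
        self.weight = 2.0 * np.pi * self.rc * self.area

        # constrained dofs: u_r on axis; u_z on midplane and end face
        fixed = set()
        for n in m.axis_nodes:
            fixed.add(2 * n)
        for n in m.midplane_nodes:
            fixed.add(2 * n + 1)
        for n in m.end_nodes:
            fixed.add(2 * n + 1)
        self.fixed = np.array(sorted(fixed), dtype=int)
        free_mask = np.ones(2 * m.n_nodes, dtype=bool)
        free_mask[self.fixed] = False
        self.free = np.flatnonzero(free_mask)
        self.dofmap = np.empty((m.n_elements, 6), dtype=int)
        self.dofmap[:, 0::2] = 2 * m.elements
        self.dofmap[:, 1::2] = 2 * m.elements + 1

    # ------------------------------------------------------------------
    def element_dofs(self, U):
        """Element-local displacement array (E, 3, 2) from the global vector."""
        return U.reshape(-1, 2)[self.mesh.elements]

    def kinematics(self, U):
        """Deformation gradient components per element from nodal dofs."""
        return self._kinematics_local(self.element_dofs(U))

    def _kinematics_local(self, ue):
        dur = np.einsum("eai,ea->ei", self.grads, ue[:, :, 0])
        duz = np.einsum("eai,ea->ei", self.grads, ue[:, :, 1])
        Frr = 1.0 + dur[:, 0]
        Frz = dur[:, 1]
        Fzr = duz[:, 0]
        Fzz = 1.0 + duz[:, 1]
        ur_c = ue[:, :, 0].mean(axis=1)
        Ftt = 1.0 + ur_c / self.rc
        return Frr, Frz, Fzr, Fzz, Ftt

    def _piola(self, U, sigma_act):
        return self._piola_local(self.element_dofs(U), sigma_act)

    def _piola_local(self, ue, sigma_act):
        """First Piola-Kirchhoff components (passive + active) per element.

        ``sigma_act``: (E, 4) active Cauchy components (rr, zz, tt, rz).
        Returns None if any element is inverted (J <= 0).
        """
        Frr, Frz, Fzr, Fzz, Ftt = self._kinematics_local(ue)
        det2 = Frr * Fzz - Frz * Fzr
        J = det2 * Ftt
        if np.any(J <= 1e-12):
            return None
        # F^{-T} in-plane block and hoop component
        iT_rr = Fzz / det2
        iT_rz = -Fzr / det2
        iT_zr = -Frz / det2
        iT_zz = Frr / det2
        iT_tt = 1.0 / Ftt
        lnJ = np.log(J)
        c = self.lam * lnJ - self.mu
        P_rr = self.mu * Frr + c * iT_rr
        P_rz = self.mu * Frz + c * iT_rz
        P_zr = self.mu * Fzr + c * iT_zr
        P_zz = self.mu * Fzz + c * iT_zz
        P_tt = self.mu * Ftt + c * iT_tt
        if sigma_act is not None:
            s_rr, s_zz, s_tt, s_rz = sigma_act.T
            P_rr += J * (s_rr * iT_rr + s_rz * iT_zr)
            P_rz += J * (s_rr * iT_rz + s_rz * iT_zz)
            P_zr += J * (s_rz * iT_rr + s_zz * iT_zr)
            P_zz += J * (s_rz * iT_rz + s_zz * iT_zz)
            P_tt += J * s_tt * iT_tt
        return P_rr, P_rz, P_zr, P_zz, P_tt

    def element_residual(self, U, sigma_act):
        """Internal-force contributions (E, 6) or None on inversion."""
        return self._element_residual_local(self.element_dofs(U), sigma_act)

    def _element_residual_local(self, ue, sigma_act):
        piola = self._piola_local(ue, sigma_act)
        if piola is None:
            return None
        P_rr, P_rz, P_zr, P_zz, P_tt = piola
        G = self.grads
        w = self.weight
        R = np.empty((self.mesh.n_elements, 6))
        for a in range(3):
            R[:, 2 * a] = w * (P_rr * G[:, a, 0] + P_rz * G[:, a, 1]
                               + P_tt / (3.0 * self.rc))
            R[:, 2 * a + 1] = w * (P_zr * G[:, a, 0] + P_zz * G[:, a, 1])
        return R

    def residual(self, U, sigma_act):
        Re = self.element_residual(U, sigma_act)
        if Re is None:
            return None
        R = np.zeros(2 * self.mesh.n_nodes)
        np.add.at(R, self.dofmap, Re)
        return R

    def tangent(self, U, sigma_act, h: float = 1e-6):
        """Finite-difference consistent tangent, assembled sparse.

        Central differences on element-local dofs (each element perturbed
        independently), vectorized over all elements.
        """
        m = self.mesh
        ue = self.element_dofs(U)
        scale = h * (1.0 + np.abs(U).max())
        Ke = np.empty((m.n_elements, 6, 6))
        for d in range(6):
            a, i = divmod(d, 2)
            up = ue.copy()
            up[:, a, i] += scale
            um = ue.copy()
            um[:, a, i] -= scale
            rp = self._element_residual_local(up, sigma_act)
            rm = self._element_residual_local(um, sigma_act)
            if rp is None or rm is None:
                return None
            Ke[:, :, d] = (rp - rm) / (2 * scale)
        rows = np.repeat(self.dofmap, 6, axis=1).ravel()
        cols = np.tile(self.dofmap, (1, 6)).ravel()
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(2 * m.n_nodes, 2 * m.n_nodes)).tocsr()
        return K

    # ------------------------------------------------------------------
    def newton(self, U0, sigma_act, max_iter=MAX_NEWTON):
        """Newton solve at fixed active stress; returns U or None."""
        U = U0.copy()
        R = self.residual(U, sigma_act)
        if R is None:
            return None
        ref = max(np.linalg.norm(R[self.free]), ABS_TOL)
        for _ in range(max_iter):
            norm = np.linalg.norm(R[self.free])
            if norm <= REL_TOL * ref or norm <= ABS_TOL:
                return U
            K = self.tangent(U, sigma_act)
            if K is None:
                return None
            Kff = K[self.free][:, self.free]
            try:
                du = spla.spsolve(Kff.tocsc(), -R[self.free])
            except Exception:
                return None
            if not np.all(np.isfinite(du)):
                return None
            # backtracking line search on the residual norm
            step = 1.0
            for _ in range(8):
                Utry = U.copy()
                Utry[self.free] += step * du
                Rtry = self.residual(Utry, sigma_act)
                if Rtry is not None and \
                        np.linalg.norm(Rtry[self.free]) < norm * (1 - 1e-4 * step) + ABS_TOL:
                    U, R = Utry, Rtry
                    break
                step *= 0.5
            else:
                return None
        R = self.residual(U, sigma_act)
        if R is not None and np.linalg.norm(R[self.free]) <= 1e-6 * ref:
            return U
        return None


def _active_field(model: Model, rho_tensor, sigma_mt):
    """Active Cauchy components (E, 4) from cytoplasm rho and cage sigma."""
    E = model.mesh.n_elements
    s = np.zeros((E, 4))
    cyt = model.mesh.region == CYTOPLASM
    s[cyt] = rho_tensor[cyt]
    cage = model.mesh.region == CAGE
    s[cage, 0] -= sigma_mt
    s[cage, 1] -= sigma_mt
    s[cage, 2] -= sigma_mt
    return s


def _isotropic_rho(model: Model, rho0):
    E = model.mesh.n_elements
    rho = np.zeros((E, 4))
    rho[:, 0] = rho[:, 1] = rho[:, 2] = rho0
    return rho


def cauchy_stress(model: Model, U, sigma_act):
    """Total Cauchy stress components (rr, zz, tt, rz) per element."""
    piola = model._piola(U, sigma_act)
    if piola is None:
        raise SolverError("inverted element while evaluating stress")
    P_rr, P_rz, P_zr, P_zz, P_tt = piola
    Frr, Frz, Fzr, Fzz, Ftt = model.kinematics(U)
    J = (Frr * Fzz - Frz * Fzr) * Ftt
    s_rr = (P_rr * Frr + P_rz * Frz) / J
    s_zz = (P_zr * Fzr + P_zz * Fzz) / J
    s_rz = (P_rr * Fzr + P_rz * Fzz) / J
    s_tt = P_tt * Ftt / J
    return np.column_stack([s_rr, s_zz, s_tt, s_rz])


def polarized_rho(model: Model, U, sigma_act, rho0, lam):
    """Concentrate contractility along the max-principal-stress direction.

    Replaces rho_ij with rho0' (lam n (x) n + (1-lam)/2 (I - n (x) n)) where
    n is the element's maximum-principal-stress direction and rho0' = 3 rho0
    keeps the average motor density (tr rho / 3) unchanged.
    """
    sig = cauchy_stress(model, U, sigma_act)
    E = model.mesh.n_elements
    rho = np.zeros((E, 4))
    rho0p = 3.0 * rho0
    cyt = np.flatnonzero(model.mesh.region == CYTOPLASM)
    for e in cyt:
        s_rr, s_zz, s_tt, s_rz = sig[e]
        M = np.array([[s_rr, s_rz], [s_rz, s_zz]])
        evals, evecs = np.linalg.eigh(M)
        if s_tt >= evals[1]:
            # hoop direction carries the maximum principal stress
            rho[e] = [rho0p * (1 - lam) / 2, rho0p * (1 - lam) / 2, rho0p * lam, 0.0]
        else:
            n = evecs[:, 1]
            nn = np.outer(n, n)
            rho[e, 0] = rho0p * (lam * nn[0, 0] + (1 - lam) / 2 * (1 - nn[0, 0]))
            rho[e, 1] = rho0p * (lam * nn[1, 1] + (1 - lam) / 2 * (1 - nn[1, 1]))
            rho[e, 2] = rho0p * (1 - lam) / 2
            rho[e, 3] = rho0p * (lam - (1 - lam) / 2) * nn[0, 1]
    return rho


@dataclass
class MechSolution:
    """Converged state with shape, stress-field and probe summaries."""

    model: Model
    U: np.ndarray                  # nodal displacements (2N,)
    sigma: np.ndarray              # element Cauchy stress (E, 4)
    sigma_act: np.ndarray          # active Cauchy field used at equilibrium
    rho0: float
    sigma_mt: float
    polarized: bool

    # ---- nuclear shape -------------------------------------------------
    @property
    def nuclear_aspect_ratio(self) -> float:
        m = self.model.mesh
        u = self.U.reshape(-1, 2)
        a = self.model.geometry.nucleus_initial_radius
        half_len = a + u[m.nucleus_pole, 1]
        half_wid = a + u[m.nucleus_equator, 0]
        return float(half_len / half_wid)

    @property
    def nuclear_volume_change(self) -> float:
        """Percent change of nuclear volume vs the stress-free state."""
        m = self.model.mesh
        Frr, Frz, Fzr, Fzz, Ftt = self.model.kinematics(self.U)
        J = (Frr * Fzz - Frz * Fzr) * Ftt
        nuc = (m.region == NUCLEOPLASM) | (m.region == LAMINA)
        w = self.model.weight[nuc]
        return float(100.0 * ((J[nuc] * w).sum() / w.sum() - 1.0))

    @property
    def cell_axial_strain(self) -> float:
        m = self.model.mesh
        u = self.U.reshape(-1, 2)
        return float(np.max(np.abs(u[m.end_nodes, 1]))
                     / self.model.geometry.cell_half_length)

    # ---- lamina principal-stress location ------------------------------
    def lamina_max_principal_location(self):
        """(s, value): normalized arc coordinate of the lamina element with
        the maximum principal (most tensile) stress; s = 0 equator, 1 tip."""
        m = self.model.mesh
        lam_els = np.flatnonzero(m.region == LAMINA)
        best_s, best_v = 0.0, -np.inf
        p = m.nodes[m.elements[lam_els]].mean(axis=1)
        theta = np.arctan2(p[:, 1], p[:, 0])
        for k, e in enumerate(lam_els):
            s_rr, s_zz, s_tt, s_rz = self.sigma[e]
            M = np.array([[s_rr, s_rz], [s_rz, s_zz]])
            v = max(np.linalg.eigvalsh(M)[1], s_tt)
            if v > best_v:
                best_v = v
                best_s = theta[k] / (np.pi / 2)
        return float(best_s), float(best_v)

    def summary(self) -> dict:
        probes = probe_stresses(self)
        s_loc, s_val = self.lamina_max_principal_location()
        return {
            "nuclear_aspect_ratio": self.nuclear_aspect_ratio,
            "nuclear_volume_change_pct": self.nuclear_volume_change,
            "rho0": self.rho0, "sigma_mt": self.sigma_mt,
            "polarized": self.polarized,
            "max_principal_stress_location_on_lamina": s_loc,
            "max_principal_stress_on_lamina": s_val,
            **probes,
        }


def build_model(geometry: MechGeometry | None = None,
                materials: MechMaterials | None = None,
                active: ActiveState | None = None,
                refine: float = 1.0) -> Model:
    """Assemble mesh, materials and boundary conditions."""
    return Model(geometry or MechGeometry(), materials or MechMaterials(),
                 active or ActiveState(), refine=refine)


def solve_ramp(model: Model, n_steps: int | None = None,
               return_sequence: bool = False):
    """Quasi-static ramp of (rho0, sigma_MT) from zero, then polarization.

    Both loads ramp proportionally from the stress-free configuration.
    After the isotropic ramp the contractility is concentrated along the
    local maximum-principal-stress direction and the model is re-solved.
    Non-convergence triggers step halving; if a level still fails, a
    SolverError carrying the last converged state is raised.
    """
    act = model.active
    n = n_steps or act.n_steps
    U = np.zeros(2 * model.mesh.n_nodes)
    seq = []
    levels = list(np.linspace(1.0 / n, 1.0, n))
    i = 0
    halvings = 0
    prev = 0.0
    sig_act = _active_field(model, _isotropic_rho(model, 0.0), 0.0)
    while i < len(levels):
        s = levels[i]
        rho = _isotropic_rho(model, s * act.rho0)
        sig_try = _active_field(model, rho, s * act.sigma_mt)
        Unew = model.newton(U, sig_try)
        if Unew is None:
            halvings += 1
            if halvings > 12:
                raise SolverError(
                    f"ramp failed at load fraction {s:.3f}",
                    last_converged=_make_solution(model, U, sig_act, prev, False))
            levels.insert(i, 0.5 * (prev + s))
            continue
        U = Unew
        sig_act = sig_try
        prev = s
        i += 1
        if return_sequence:
            seq.append(_make_solution(model, U, sig_act, s, False))

    polarized = False
    if act.polarization == "single" and act.rho0 > 0:
        rho_iso = _isotropic_rho(model, act.rho0)
        sig_iso = _active_field(model, rho_iso, act.sigma_mt)
        rho_pol = polarized_rho(model, U, sig_iso, act.rho0,
                                act.polarization_lambda)
        # blend toward the polarized state if a direct solve struggles
        for frac in (1.0, 0.5, 0.25):
            rho_try = frac * rho_pol + (1 - frac) * rho_iso
            sig_try = _active_field(model, rho_try, act.sigma_mt)
            Unew = model.newton(U, sig_try)
            if Unew is not None:
                U = Unew
                sig_act = sig_try
                if frac < 1.0:   # continue the remaining blend stepwise
                    for f2 in np.linspace(frac, 1.0, 4)[1:]:
                        rho_try = f2 * rho_pol + (1 - f2) * rho_iso
                        sig_try = _active_field(model, rho_try, act.sigma_mt)
                        Unew = model.newton(U, sig_try)
                        if Unew is None:
                            raise SolverError(
                                "polarization blend failed",
                                last_converged=_make_solution(
                                    model, U, sig_act, 1.0, False))
                        U = Unew
                        sig_act = sig_try
                polarized = True
                break
        if not polarized:
            raise SolverError("polarization step failed",
                              last_converged=_make_solution(model, U, sig_act,
                                                            1.0, False))

    sol = _make_solution(model, U, sig_act, 1.0, polarized)
    if return_sequence:
        seq.append(sol)
        return seq
    return sol


def _make_solution(model, U, sig_act, load_fraction, polarized):
    act = model.active
    sigma = cauchy_stress(model, U, sig_act)
    return MechSolution(model=model, U=U, sigma=sigma, sigma_act=sig_act,
                        rho0=load_fraction * act.rho0,
                        sigma_mt=load_fraction * act.sigma_mt,
                        polarized=polarized)


#: angular half-width (degrees) of the tip/equator probe sectors
PROBE_SECTOR_DEG = 20.0
#: radial reach (um) of the near-cage cytoplasm band used for tension probes
PROBE_BAND_UM = 1.5


def probe_stresses(solution: MechSolution) -> dict:
    """Element-averaged axial stresses at the four named probe sites.

    Myofibril tension: axial Cauchy stress in cytoplasm elements in a
    1.5 um band outside the cage, at the cage short tip (equatorial sector,
    maximum) and at the cage long tip (polar sector, minimum — this site
    sits in the axial stress shadow of the compressed cage column, see the
    methods note).  MT axial compression: -sigma_zz averaged over cage
    elements in the polar sector (nucleus long tip) and the equatorial
    sector (nucleus short tip).
    """
    model = solution.model
    m = model.mesh
    from .mesh import _ellipse_radius
    cent = m.nodes[m.elements].mean(axis=1)
    theta = np.degrees(np.arctan2(cent[:, 1], cent[:, 0]))
    rad = np.hypot(cent[:, 0], cent[:, 1])
    th = np.arctan2(cent[:, 1], cent[:, 0])
    r_cage = _ellipse_radius(th, *model.geometry.cage_semi_axes)
    near = (m.region == CYTOPLASM) & (rad < r_cage + PROBE_BAND_UM)
    cage = m.region == CAGE
    eq = theta < PROBE_SECTOR_DEG
    pole = theta > 90.0 - PROBE_SECTOR_DEG
    sig_zz = solution.sigma[:, 1]

    def avg(mask):
        return float(sig_zz[mask].mean()) if mask.any() else float("nan")

    return {
        "myofibril_tension_max": avg(near & eq),
        "myofibril_tension_min": avg(near & pole),
        "mt_axial_compression_max": -avg(cage & pole),
        "mt_axial_compression_min": -avg(cage & eq),
    }
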