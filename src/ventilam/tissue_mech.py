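"""Quasi-static mechanics of a three-layer airway wall cross-section.

The wall is an axisymmetric annulus of three concentric layers —
epithelium, connective tissue and airway smooth muscle (ASM) — loaded by
lumen pressure on the inner boundary and tethered to the surrounding
parenchyma by an elastic foundation (spring traction ``-k u``) on the
outer boundary. The two inner layers are compressible Neo-Hookean,

    W = (mu/2) (I1_bar - 3) + (1/d) (J - 1)^2,

with ``I1_bar = J^(-2/3) I1`` the deviatoric first invariant; the ASM is
linear elastic. Plane strain is assumed (a long tube deforming radially),
so the displacement field reduces to the radial profile u(r), and the
problem is solved by minimising the total potential energy with a 1D
finite-element discretisation and Newton iteration. The scalar handed to
the cellular stage is the mean hoop strain of the epithelial layer.

Inertia is neglected: breathing frequencies are orders of magnitude below
the wall's resonance, so the wall tracks the peak-cycle pressure
quasi-statically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

#: elastic-foundation (parenchymal tethering) stiffness, traction per displacement
FOUNDATION_K = 600.0


@dataclass(frozen=True)
class MaterialNeoHookean:
    """Compressible Neo-Hookean material: shear-type constant mu (Pa) and
    volumetric penalty d (1/Pa); small-strain bulk modulus K = 2/d."""

    mu: float
    d: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.d <= 0:
            raise ValueError("d must be positive")

    @property
    def bulk_modulus(self) -> float:
        return 2.0 / self.d

    @property
    def lame_lambda(self) -> float:
        """Equivalent small-strain Lame lambda = K - 2 mu / 3."""
        return self.bulk_modulus - 2.0 * self.mu / 3.0


def near_incompressible(mu: float, nu: float = 0.49) -> MaterialNeoHookean:
    """Neo-Hookean material with d set from an effective Poisson ratio."""
    k = 2.0 * mu * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
    return MaterialNeoHookean(mu=mu, d=2.0 / k)


@dataclass(frozen=True)
class MaterialLinear:
    """Isotropic linear-elastic material (used for the ASM layer)."""

    young_modulus: float
    poisson: float = 0.45

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.poisson < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")

    @property
    def lame_lambda(self) -> float:
        e, nu = self.young_modulus, self.poisson
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson))


@dataclass(frozen=True)
class WallLayer:
    name: str
    thickness: float
    material: MaterialNeoHookean | MaterialLinear

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be positive")


@dataclass(frozen=True)
class WallSection:
    """Three-layer annulus: inner radius, ordered layers (inner to outer)
    and the elastic-foundation stiffness on the outer boundary."""

    inner_radius: float
    layers: tuple[WallLayer, ...]
    foundation_k: float = FOUNDATION_K

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError("inner radius must be positive")
        if not self.layers:
            raise ValueError("at least one layer required")
        if self.foundation_k < 0:
            raise ValueError("foundation stiffness must be >= 0")

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + sum(l.thickness for l in self.layers)

    @property
    def interfaces(self) -> np.ndarray:
        """Radii of layer boundaries, inner_radius .. outer_radius."""
        return self.inner_radius + np.concatenate(
            [[0.0], np.cumsum([l.thickness for l in self.layers])])


@dataclass(frozen=True)
class WallSolution:
    """Converged radial equilibrium of a pressurised wall section."""

    r: np.ndarray               # nodal radii (reference), m
    u: np.ndarray               # radial displacement, m
    eps_r: np.ndarray           # nodal radial strain du/dr
    eps_theta: np.ndarray       # nodal hoop strain u/r
    sigma_r: np.ndarray         # radial Cauchy-type stress at nodes, Pa
    sigma_theta: np.ndarray     # hoop stress at nodes, Pa
    epithelial_strain: float    # mean hoop strain of the epithelial layer
    internal_energy: float      # strain + foundation energy per unit length, J/m
    iterations: int
    residual_norm: float


def neo_hookean_energy(i1, j, m: MaterialNeoHookean):
    """Strain-energy density W = (mu/2)(I1_bar - 3) + (1/d)(J - 1)^2, Pa.

    ``i1`` is the deviatoric first invariant I1_bar. Raises on a
    non-positive Jacobian (inverted element).
    """
    j = np.asarray(j, dtype=float)
    if np.any(j <= 0):
        raise ValueError("Jacobian must be positive (element inversion)")
    w = 0.5 * m.mu * (np.asarray(i1, dtype=float) - 3.0) + (1.0 / m.d) * (j - 1.0) ** 2
    return float(w) if w.ndim == 0 else w


# ---------------------------------------------------------------------------
# constitutive response in principal stretches (plane strain: lam_z = 1)
# ---------------------------------------------------------------------------

def _nh_response(lam_r, lam_t, m: MaterialNeoHookean):
    """W, dW/dlam, d2W/dlam2 for plane-strain Neo-Hookean at stretches
    (lam_r, lam_t, 1). Vectorised."""
    mu, d = m.mu, m.d
    i1 = lam_r ** 2 + lam_t ** 2 + 1.0
    jac = lam_r * lam_t
    f = jac ** (-2.0 / 3.0)
    fp = -(2.0 / 3.0) * jac ** (-5.0 / 3.0)
    fpp = (10.0 / 9.0) * jac ** (-8.0 / 3.0)
    w = 0.5 * mu * (f * i1 - 3.0) + (1.0 / d) * (jac - 1.0) ** 2
    w_r = 0.5 * mu * (fp * lam_t * i1 + 2.0 * f * lam_r) + (2.0 / d) * (jac - 1.0) * lam_t
    w_t = 0.5 * mu * (fp * lam_r * i1 + 2.0 * f * lam_t) + (2.0 / d) * (jac - 1.0) * lam_r
    w_rr = 0.5 * mu * (fpp * lam_t ** 2 * i1 + 4.0 * fp * lam_r * lam_t + 2.0 * f) \
        + (2.0 / d) * lam_t ** 2
    w_tt = 0.5 * mu * (fpp * lam_r ** 2 * i1 + 4.0 * fp * lam_r * lam_t + 2.0 * f) \
        + (2.0 / d) * lam_r ** 2
    w_rt = 0.5 * mu * (fpp * lam_r * lam_t * i1 + fp * (i1 + 2.0 * lam_r ** 2 + 2.0 * lam_t ** 2)) \
        + (2.0 / d) * (lam_r * lam_t + jac - 1.0)
    return w, w_r, w_t, w_rr, w_tt, w_rt


def _lin_response(lam_r, lam_t, m: MaterialLinear):
    """Small-strain plane-strain response in the same (stretch) variables."""
    lam, g = m.lame_lambda, m.shear_modulus
    er, et = lam_r - 1.0, lam_t - 1.0
    tr = er + et
    w = 0.5 * lam * tr ** 2 + g * (er ** 2 + et ** 2)
    w_r = lam * tr + 2.0 * g * er
    w_t = lam * tr + 2.0 * g * et
    one = np.ones_like(np.asarray(lam_r, dtype=float))
    return w, w_r, w_t, (lam + 2.0 * g) * one, (lam + 2.0 * g) * one, lam * one


def _mesh(section: WallSection, n_nodes: int):
    """Nodal radii with interface-conforming, thickness-proportional spacing."""
    bounds = section.interfaces
    total = bounds[-1] - bounds[0]
    r_parts, mat_ids = [], []
    for i, layer in enumerate(section.layers):
        n_el = max(4, int(round((n_nodes - 1) * layer.thickness / total)))
        seg = np.linspace(bounds[i], bounds[i + 1], n_el + 1)
        r_parts.append(seg[:-1] if i < len(section.layers) - 1 else seg)
        mat_ids.extend([i] * n_el)
    return np.concatenate(r_parts), np.asarray(mat_ids)


def solve_wall(section: WallSection, lumen_pressure: float, n_nodes: int = 200,
               tol: float = 1e-10, max_iter: int = 50) -> WallSolution:
    """Radial equilibrium of the layered annulus under lumen pressure.

    Minimises total potential energy (strain energy + foundation energy -
    follower-pressure potential) over the nodal radial displacements with
    linear 1D finite elements (two-point Gauss quadrature) and a full
    Newton iteration with analytic tangent. Convergence is declared when
    the residual norm falls below ``tol`` relative to the applied-load
    scale.
    """
    if lumen_pressure < 0:
        raise ValueError("lumen pressure must be >= 0 (inflation case)")
    r, mat_ids = _mesh(section, n_nodes)
    n = r.size
    u = np.zeros(n)
    a, b = r[0], r[-1]
    h = np.diff(r)
    gp = np.array([0.5 - 0.5 / math.sqrt(3.0), 0.5 + 0.5 / math.sqrt(3.0)])
    # Gauss-point radii and shape values, shape (n_el, 2)
    rg = r[:-1, None] + h[:, None] * gp[None, :]
    n1 = 1.0 - gp[None, :] + 0.0 * rg
    n2 = gp[None, :] + 0.0 * rg
    wgt = 0.5 * h[:, None] * np.ones_like(rg)  # weight * jacobian
    # load scale for the relative residual
    scale = max(2.0 * math.pi * a * lumen_pressure, 1e-12)

    def response(lam_r, lam_t):
        out = [np.empty_like(lam_r) for _ in range(6)]
        for mi, layer in enumerate(section.layers):
            sel = mat_ids == mi
            if isinstance(layer.material, MaterialNeoHookean):
                vals = _nh_response(lam_r[sel], lam_t[sel], layer.material)
            else:
                vals = _lin_response(lam_r[sel], lam_t[sel], layer.material)
            for o, v in zip(out, vals):
                o[sel] = v
        return out

    def assemble(u):
        ue1, ue2 = u[:-1, None], u[1:, None]
        lam_r = np.broadcast_to(1.0 + (ue2 - ue1) / h[:, None], rg.shape).copy()
        lam_t = 1.0 + (n1 * ue1 + n2 * ue2) / rg
        if np.any(lam_r * lam_t <= 0):
            raise FloatingPointError("element inversion during Newton iteration")
        w, w_r, w_t, w_rr, w_tt, w_rt = response(lam_r, lam_t)
        two_pi_r = 2.0 * math.pi * rg * wgt
        # gradient: dPi/du_i = sum_gp 2 pi r w [W_r B_r + W_t B_t]
        br1, br2 = -1.0 / h[:, None], 1.0 / h[:, None]
        bt1, bt2 = n1 / rg, n2 / rg
        g1 = (two_pi_r * (w_r * br1 + w_t * bt1)).sum(axis=1)
        g2 = (two_pi_r * (w_r * br2 + w_t * bt2)).sum(axis=1)
        grad = np.zeros_like(u)
        np.add.at(grad, np.arange(u.size - 1), g1)
        np.add.at(grad, np.arange(1, u.size), g2)
        # tangent (tridiagonal): pairwise products of B-vectors
        k11 = (two_pi_r * (w_rr * br1 * br1 + w_rt * (br1 * bt1 + bt1 * br1) + w_tt * bt1 * bt1)).sum(axis=1)
        k12 = (two_pi_r * (w_rr * br1 * br2 + w_rt * (br1 * bt2 + bt1 * br2) + w_tt * bt1 * bt2)).sum(axis=1)
        k22 = (two_pi_r * (w_rr * br2 * br2 + w_rt * (br2 * bt2 + bt2 * br2) + w_tt * bt2 * bt2)).sum(axis=1)
        diag = np.zeros_like(u)
        np.add.at(diag, np.arange(u.size - 1), k11)
        np.add.at(diag, np.arange(1, u.size), k22)
        off = k12.copy()
        # external loads: follower pressure at inner node, foundation at outer
        grad[0] -= 2.0 * math.pi * lumen_pressure * (a + u[0])
        diag[0] -= 2.0 * math.pi * lumen_pressure
        grad[-1] += 2.0 * math.pi * b * section.foundation_k * u[-1]
        diag[-1] += 2.0 * math.pi * b * section.foundation_k
        energy = float((two_pi_r * w).sum()) \
            + math.pi * b * section.foundation_k * u[-1] ** 2
        return grad, diag, off, energy

    # Round-off floor: residual entries are differences of terms of size
    # ~mu while the converged values are ~P, so the achievable relative
    # residual is bounded below by eps * (stiffness scale / load scale).
    mu_scale = max(getattr(l.material, "mu", 0.0) or l.material.young_modulus
                   for l in section.layers)
    floor = 64.0 * np.finfo(float).eps * mu_scale * 2.0 * math.pi * b / scale
    res_norm = math.inf
    energy = 0.0
    for it in range(max_iter + 1):
        grad, diag, off, energy = assemble(u)
        res_norm = float(np.linalg.norm(grad)) / scale
        if res_norm < max(tol, floor) or (lumen_pressure == 0.0 and not u.any()):
            break
        if it == max_iter:
            raise RuntimeError(
                f"Newton iteration did not converge in {max_iter} steps; "
                f"relative residual {res_norm:.3e}")
        ab = np.zeros((3, u.size))
        ab[0, 1:] = off
        ab[1, :] = diag
        ab[2, :-1] = off
        du = solve_banded((1, 1), ab, grad)
        u = u - du
        if np.linalg.norm(du) <= 1e-12 * max(float(np.linalg.norm(u)), 1e-300):
            grad, diag, off, energy = assemble(u)
            res_norm = float(np.linalg.norm(grad)) / scale
            break

    eps_theta = u / r
    eps_r = np.gradient(u, r)
    # nodal stresses from the constitutive response at nodal stretches
    lam_rn = 1.0 + eps_r
    lam_tn = 1.0 + eps_theta
    node_mat = np.concatenate([[mat_ids[0]], mat_ids])  # node -> adjoining element
    s_r = np.empty(n)
    s_t = np.empty(n)
    for mi, layer in enumerate(section.layers):
        sel = node_mat == mi
        if isinstance(layer.material, MaterialNeoHookean):
            _, w_r, w_t, *_ = _nh_response(lam_rn[sel], lam_tn[sel], layer.material)
            jac = lam_rn[sel] * lam_tn[sel]
            # Cauchy stress from first Piola: sigma = P lam / J (principal, plane strain)
            s_r[sel] = w_r * lam_rn[sel] / jac
            s_t[sel] = w_t * lam_tn[sel] / jac
        else:
            _, w_r, w_t, *_ = _lin_response(lam_rn[sel], lam_tn[sel], layer.material)
            s_r[sel] = w_r
            s_t[sel] = w_t
    # mean hoop strain over the epithelial (innermost) layer
    epi_outer = section.interfaces[1]
    epi_sel = r <= epi_outer * (1.0 + 1e-12)
    epi_strain = float(np.trapezoid(eps_theta[epi_sel], r[epi_sel])
                       / (r[epi_sel][-1] - r[epi_sel][0]))
    return WallSolution(r=r, u=u, eps_r=eps_r, eps_theta=eps_theta,
                        sigma_r=s_r, sigma_theta=s_t,
                        epithelial_strain=epi_strain, internal_energy=energy,
                        iterations=it, residual_norm=res_norm)


# ---------------------------------------------------------------------------
# per-generation sections and the pipeline-facing strain map
# ---------------------------------------------------------------------------

#: shear constant of the epithelial layer (inner layer of the wall), Pa
EPITHELIUM_MU = 5e6
#: stiffness ratio between inner and middle layer (inner stiffer)
INNER_MIDDLE_RATIO = 10.0
#: ASM Young's modulus, Pa (organ-scale tissue value reused)
ASM_E = 99e6


def default_materials(epithelium_mu: float = EPITHELIUM_MU,
                      inner_middle_ratio: float = INNER_MIDDLE_RATIO,
                      asm_e: float = ASM_E, asm_nu: float = 0.45,
                      nh_nu: float = 0.49):
    """Default (epithelium, connective, ASM) materials."""
    epi = near_incompressible(epithelium_mu, nh_nu)
    conn = near_incompressible(epithelium_mu / inner_middle_ratio, nh_nu)
    asm = MaterialLinear(young_modulus=asm_e, poisson=asm_nu)
    return epi, conn, asm


def wall_sections(morphology: pd.DataFrame, materials=None,
                  foundation_k: float = FOUNDATION_K) -> dict[int, WallSection]:
    """Build one WallSection per generation from the morphology table
    (columns gn, radius_m, t_epi_m, t_conn_m, t_asm_m)."""
    epi, conn, asm = materials if materials is not None else default_materials()
    sections = {}
    for _, row in morphology.iterrows():
        layers = (WallLayer("epithelium", float(row["t_epi_m"]), epi),
                  WallLayer("connective", float(row["t_conn_m"]), conn),
                  WallLayer("asm", float(row["t_asm_m"]), asm))
        sections[int(row["gn"])] = WallSection(inner_radius=float(row["radius_m"]),
                                               layers=layers, foundation_k=foundation_k)
    return sections


def strain_for_airways(peak_pressures: dict[int, float],
                       sections: dict[int, WallSection],
                       n_nodes: int = 200) -> dict[int, float]:
    """Epithelial mean hoop strain per generation at its peak-cycle pressure."""
    strains = {}
    for gn, p in peak_pressures.items():
        if gn not in sections:
            raise KeyError(f"no wall section for generation {gn}")
        strains[gn] = solve_wall(sections[gn], p, n_nodes=n_nodes).epithelial_strain
    return strains


def stiffen(material: MaterialNeoHookean, fibrosis_fraction: float,
            alpha: float) -> MaterialNeoHookean:
    """Inflammation-driven stiffening: mu' = mu (1 + alpha f), d unchanged.

    ``fibrosis_fraction`` is the fraction of the epithelial population in
    the fibrotic state at the end of the cellular run; ``alpha`` is the
    dimensionless stiffening gain.
    """
    if not (0.0 <= fibrosis_fraction <= 1.0):
        raise ValueError("fibrosis fraction must be in [0, 1]")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return replace(material, mu=material.mu * (1.0 + alpha * fibrosis_fraction))
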