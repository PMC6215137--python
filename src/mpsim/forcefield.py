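"""Forces, torques and energies of the coarse-grained model.

Four families of interactions act in the assembled system:

* **Shell elasticity** — a neo-Hookean centre-to-centre force on every mesh
  edge, a per-triangle local-area restoring force, and a harmonic radial
  tether between corresponding nodes of the two shells. Bending rigidity,
  global-area and volume conservation are deliberately absent: the membrane
  is soft and freely permeable to solvent.
* **Excluded volume** — a purely repulsive WCA (truncated-shifted
  Lennard-Jones) potential between every non-bonded pair of finite-size
  elements; the cutoff is half the sum of the two diameters, so the blobs of
  a shell form a wall the nanoparticles cannot squeeze through.
* **Dipole-dipole coupling** — direct all-pairs point-dipole interaction
  between nanoparticles (single box, no periodic images), with reduced pair
  energy ``lambda * a^3 * [e_i.e_j - 3 (e_i.n)(e_j.n)] / r^3``.
* **Zeeman coupling** — ``-xi * (e_i . h_hat)`` per particle in the applied
  field; a uniform field exerts torque but no net force.

All functions here are pure numpy and serve as the reference implementation;
the time-stepping hot loop in :mod:`mpsim._kernels` must agree with them.

Note: the local-area force follows the printed centroid-to-vertex law of the
mesh-membrane model; it is a constraint-restoring force and not the exact
gradient of a scalar area energy (the quadratic area energy reported in the
breakdown is a monitoring diagnostic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad
from scipy.interpolate import CubicSpline

from .mesh import ShellPair, TriangulatedShell
from .state import NanoparticleEnsemble, SimulationState

__all__ = [
    "ForceFieldParams",
    "NanoparticleEnsemble",
    "ForceReport",
    "stretch_forces",
    "local_area_forces",
    "tether_forces",
    "wca_energy_force",
    "magnetic_energy_forces_torques",
    "total_forces",
    "total_energy",
    "neo_hookean_force_magnitude",
    "neo_hookean_pair_energy",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Coupling constants of the model, reduced units.

    ``cshift`` equals ``eps`` so the WCA potential is continuous (zero) at
    its cutoff. Dipolar and Zeeman couplings live on the state/ensemble
    (``lambda_dd``, ``field_xi``); this object carries the non-magnetic
    constants.
    """

    ks: float = 50.0  # neo-Hookean edge constant
    kal: float = 50.0  # local-area constraint coefficient
    kh: float = 20.0  # inter-shell tether constant
    eps: float = 1.0  # WCA energy scale, kT units

    # Stiffness rationale: the membrane interfaces carry a reduced surface
    # tension of order sigma_s a^2/kT ~ 5e2, i.e. they are nearly inextensible
    # on the thermal scale. Edge/area constants of order 10-100 reproduce that
    # regime (thermal edge-length fluctuations of a few percent, an effectively
    # impermeable blob wall) while leaving the area-preserving global
    # elongation mode soft. Order-one constants make the mesh entropically
    # floppy enough for nanoparticles to squeeze between blobs.

    def __post_init__(self) -> None:
        for name in ("ks", "kal", "kh", "eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def cshift(self) -> float:
        return self.eps


# ---------------------------------------------------------------------------
# neo-Hookean edge springs


def neo_hookean_force_magnitude(r: np.ndarray, r0: np.ndarray, ks: float) -> np.ndarray:
    """Signed magnitude of the edge force; positive pulls the pair together.

    ``ks * [(x^0.5 + x^-2.5) / (x + x^-3)] * (r - r0) / r0`` with
    ``x = r / r0`` — nearly Hookean at small strain, stiffening under
    extension.
    """
    x = np.asarray(r, dtype=float) / r0
    if np.any(x <= 0):
        raise ValueError("singular configuration: coincident edge endpoints")
    kappa = (np.sqrt(x) + x**-2.5) / (x + x**-3)
    return ks * kappa * (x - 1.0)


def _nh_integrand(x: float) -> float:
    return (math.sqrt(x) + x**-2.5) / (x + x**-3) * (x - 1.0)


def neo_hookean_pair_energy(r: float, r0: float, ks: float) -> float:
    """Exact pair energy by quadrature, zero at ``r = r0`` (reference for tests)."""
    x = r / r0
    val, _ = quad(_nh_integrand, 1.0, x, limit=200)
    return ks * r0 * val


@lru_cache(maxsize=1)
def _nh_energy_spline() -> CubicSpline:
    """Tabulated dimensionless edge energy G(x) with G(1)=0, G'(x)=kappa(x)(x-1)."""
    x = np.linspace(0.05, 8.0, 8001)
    g = cumulative_trapezoid(np.vectorize(_nh_integrand)(x), x, initial=0.0)
    g -= np.interp(1.0, x, g)
    return CubicSpline(x, g)


def _stretch_arrays(
    pos: np.ndarray, edges: np.ndarray, r0: np.ndarray, ks: float
) -> np.ndarray:
    d = pos[edges[:, 1]] - pos[edges[:, 0]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise ValueError("singular configuration: zero-length edge")
    fmag = neo_hookean_force_magnitude(r, r0, ks)  # >0 attracts
    fvec = (fmag / r)[:, None] * d  # on edge[:,0], toward edge[:,1] when stretched
    forces = np.zeros_like(pos)
    np.add.at(forces, edges[:, 0], fvec)
    np.add.at(forces, edges[:, 1], -fvec)
    return forces


def _stretch_energy_arrays(
    pos: np.ndarray, edges: np.ndarray, r0: np.ndarray, ks: float
) -> float:
    r = np.linalg.norm(pos[edges[:, 1]] - pos[edges[:, 0]], axis=1)
    return float(ks * np.sum(r0 * _nh_energy_spline()(r / r0)))


def stretch_forces(pair: ShellPair, p: ForceFieldParams) -> tuple[np.ndarray, np.ndarray]:
    """Neo-Hookean edge forces on the outer and inner shells."""
    return (
        _stretch_arrays(pair.outer.positions, pair.outer.edges, pair.outer.r0_edge, p.ks),
        _stretch_arrays(pair.inner.positions, pair.inner.edges, pair.inner.r0_edge, p.ks),
    )


# ---------------------------------------------------------------------------
# local-area constraint


def _area_arrays(
    pos: np.ndarray, triangles: np.ndarray, S0: np.ndarray, kal: float
) -> np.ndarray:
    p = pos[triangles]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    S = 0.5 * np.linalg.norm(cross, axis=1)
    if np.any(S <= 0):
        raise ValueError("degenerate triangle: zero current area")
    centroid = p.mean(axis=1)
    coef = -kal * (S - S0) / S  # <0 when inflated: pull vertices inward
    forces = np.zeros_like(pos)
    for v in range(3):
        w = p[:, v] - centroid
        wn = np.linalg.norm(w, axis=1)
        fvec = (coef / wn)[:, None] * w
        np.add.at(forces, triangles[:, v], fvec)
    return forces


def local_area_forces(shell: TriangulatedShell, p: ForceFieldParams) -> np.ndarray:
    """Per-node restoring forces opposing deviations of each triangle's area.

    Vertex ``i`` of triangle ``k`` receives ``-kal (S_k - S0_k)/S_k`` along
    the unit vector from the triangle centroid to the vertex.
    """
    return _area_arrays(shell.positions, shell.triangles, shell.S0_tri, p.kal)


def _area_energy_arrays(
    pos: np.ndarray, triangles: np.ndarray, S0: np.ndarray, kal: float
) -> float:
    p = pos[triangles]
    S = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    return float(0.5 * kal * np.sum((S - S0) ** 2 / S0))


# ---------------------------------------------------------------------------
# inter-shell tethers


def tether_forces(pair: ShellPair, p: ForceFieldParams) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic radial springs between corresponding nodes of the two shells."""
    pin = pair.inner.positions[pair.correspondence]
    d = pin - pair.outer.positions  # outer -> matched inner
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise ValueError("singular configuration: coincident tethered nodes")
    fmag = p.kh * (r - pair.r0_tether)  # >0 pulls the pair together
    f_out = (fmag / r)[:, None] * d
    f_in = np.zeros_like(pair.inner.positions)
    np.add.at(f_in, pair.correspondence, -f_out)
    return f_out, f_in


def _tether_energy(pair: ShellPair, p: ForceFieldParams) -> float:
    pin = pair.inner.positions[pair.correspondence]
    r = np.linalg.norm(pin - pair.outer.positions, axis=1)
    return float(0.5 * p.kh * np.sum((r - pair.r0_tether) ** 2))


# ---------------------------------------------------------------------------
# WCA excluded volume


def wca_energy_force(r, d_i: float, d_j: float, eps: float):
    """WCA pair energy and force magnitude at centre distance ``r``.

    Cutoff ``R = (d_i + d_j)/2``, ``sigma = R / 2^(1/6)``; the shift
    ``cshift = eps`` makes U continuous (zero) at the cutoff. The returned
    force magnitude is positive (purely repulsive) and zero at and beyond
    the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("singular configuration: zero centre-to-centre distance")
    rcut = 0.5 * (d_i + d_j)
    sigma = rcut / 2.0 ** (1.0 / 6.0)
    inside = r < rcut
    s6 = np.where(inside, (sigma / np.where(inside, r, 1.0)) ** 6, 0.0)
    u = np.where(inside, 4.0 * eps * (s6 * s6 - s6) + eps, 0.0)
    f = np.where(inside, 24.0 * eps * (2.0 * s6 * s6 - s6) / np.where(inside, r, 1.0), 0.0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def _wca_all_pairs(
    pos: np.ndarray, diam: np.ndarray, eps: float, excluded: set[tuple[int, int]]
) -> tuple[float, np.ndarray]:
    """Energy and forces of WCA over all element pairs minus exclusions."""
    n = len(pos)
    d = pos[None, :, :] - pos[:, None, :]
    r = np.linalg.norm(d, axis=2)
    rcut = 0.5 * (diam[:, None] + diam[None, :])
    iu, ju = np.triu_indices(n, k=1)
    mask = r[iu, ju] < rcut[iu, ju]
    if excluded:
        excl = np.array([i * n + j for i, j in excluded])
        mask &= ~np.isin(iu * n + ju, excl)
    ii, jj = iu[mask], ju[mask]
    if len(ii) == 0:
        return 0.0, np.zeros_like(pos)
    rij = r[ii, jj]
    if np.any(rij == 0):
        raise ValueError("singular configuration: overlapping element centres")
    sigma = rcut[ii, jj] / 2.0 ** (1.0 / 6.0)
    s6 = (sigma / rij) ** 6
    u = float(np.sum(4.0 * eps * (s6 * s6 - s6) + eps))
    fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) / rij
    fvec = (fmag / rij)[:, None] * d[ii, jj]  # direction j - i... see below
    # d[i, j] = pos[j] - pos[i]; repulsion pushes i away from j: force on i is -fvec
    forces = np.zeros_like(pos)
    np.add.at(forces, ii, -fvec)
    np.add.at(forces, jj, fvec)
    return u, forces


# ---------------------------------------------------------------------------
# magnetics


def magnetic_energy_forces_torques(
    ens: NanoparticleEnsemble, field_vec: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Dipole-dipole plus Zeeman energy, forces and torques.

    Direct all-pairs summation (no cutoff, no periodic images). The torque
    on particle ``i`` is ``e_i x h_i`` where ``h_i`` is the reduced local
    field (applied plus dipolar) conjugate to the orientation.
    """
    m = ens.n_particles
    field_vec = np.asarray(field_vec, dtype=float)
    if m == 0:
        z = np.zeros((0, 3))
        return 0.0, z, z
    lam_a3 = ens.lambda_dd * ens.diameter**3
    e = ens.orientations
    pos = ens.positions
    # Zeeman
    u = -float(np.sum(e @ field_vec))
    hloc = np.broadcast_to(field_vec, (m, 3)).copy()
    forces = np.zeros((m, 3))
    if m > 1 and lam_a3 != 0.0:
        d = pos[None, :, :] - pos[:, None, :]  # d[i, j] = r_j - r_i
        r = np.linalg.norm(d, axis=2)
        np.fill_diagonal(r, np.inf)
        if np.any(r == 0):
            raise ValueError("singular configuration: coincident dipole centres")
        nhat = d / r[:, :, None]
        ee = e @ e.T  # e_i . e_j
        en = np.einsum("id,ijd->ij", e, nhat)  # e_i . n_ij
        ne = -en.T  # e_j . n_ij  (n_ji = -n_ij)
        inv_r3 = r**-3.0
        u += 0.5 * lam_a3 * float(np.sum((ee - 3.0 * en * ne) * inv_r3))
        # force on j from i: (3 lam a^3 / r^4) [ (e_i.e_j) n + (e_i.n) e_j
        #                    + (e_j.n) e_i - 5 (e_i.n)(e_j.n) n ]
        pref = 3.0 * lam_a3 * r**-4.0
        fj = (
            (ee - 5.0 * en * ne)[:, :, None] * nhat
            + en[:, :, None] * e[None, :, :]
            + ne[:, :, None] * e[:, None, :]
        ) * pref[:, :, None]
        forces += fj.sum(axis=0)  # total force on j summed over i
        # dipolar contribution to the local field on i:
        #   h_i = lam a^3 sum_j [ 3 (e_j.n) n - e_j ] / r^3
        hdd = (3.0 * ne)[:, :, None] * nhat - e[None, :, :]
        hloc += lam_a3 * np.sum(hdd * inv_r3[:, :, None], axis=1)
    torques = np.cross(e, hloc)
    return u, forces, torques


# ---------------------------------------------------------------------------
# assembly


@dataclass
class ForceReport:
    """Forces on every element plus a per-term energy breakdown."""

    f_outer: np.ndarray
    f_inner: np.ndarray
    f_mnp: np.ndarray
    torques: np.ndarray
    energies: dict[str, float]


def _pack_positions(state: SimulationState) -> tuple[np.ndarray, np.ndarray]:
    pair, ens = state.pair, state.ensemble
    pos = np.vstack([pair.outer.positions, pair.inner.positions, ens.positions])
    n = pair.outer.n_nodes
    diam = np.concatenate(
        [
            np.full(n, pair.outer.blob_diameter),
            np.full(n, pair.inner.blob_diameter),
            np.full(ens.n_particles, ens.diameter),
        ]
    )
    return pos, diam


def _bonded_exclusions(pair: ShellPair) -> set[tuple[int, int]]:
    """Edge-connected blob pairs, excluded from WCA (bonded exclusion)."""
    n = pair.outer.n_nodes
    excl = {(int(i), int(j)) for i, j in pair.outer.edges}
    excl |= {(int(i) + n, int(j) + n) for i, j in pair.inner.edges}
    return excl


def total_forces(state: SimulationState, p: ForceFieldParams) -> ForceReport:
    """All forces and torques acting in the assembled system.

    Blobs feel elasticity plus excluded volume; nanoparticles feel excluded
    volume plus (when ``state.magnetics_on``) dipolar and Zeeman couplings.
    Action-reaction holds pairwise, so the net force on the closed system in
    a uniform field is zero.
    """
    pair, ens = state.pair, state.ensemble
    n = pair.outer.n_nodes
    f_out_s, f_in_s = stretch_forces(pair, p)
    f_out_a = local_area_forces(pair.outer, p)
    f_in_a = local_area_forces(pair.inner, p)
    f_out_t, f_in_t = tether_forces(pair, p)

    pos, diam = _pack_positions(state)
    u_wca, f_wca = _wca_all_pairs(pos, diam, p.eps, _bonded_exclusions(pair))

    f_outer = f_out_s + f_out_a + f_out_t + f_wca[:n]
    f_inner = f_in_s + f_in_a + f_in_t + f_wca[n : 2 * n]
    f_mnp = f_wca[2 * n :].copy()

    if state.magnetics_on:
        u_mag, f_dd, torques = magnetic_energy_forces_torques(ens, state.field_vector)
        f_mnp += f_dd
    else:
        u_mag = 0.0
        torques = np.zeros((ens.n_particles, 3))

    energies = {
        "stretch": _stretch_energy_arrays(
            pair.outer.positions, pair.outer.edges, pair.outer.r0_edge, p.ks
        )
        + _stretch_energy_arrays(
            pair.inner.positions, pair.inner.edges, pair.inner.r0_edge, p.ks
        ),
        "area": _area_energy_arrays(
            pair.outer.positions, pair.outer.triangles, pair.outer.S0_tri, p.kal
        )
        + _area_energy_arrays(
            pair.inner.positions, pair.inner.triangles, pair.inner.S0_tri, p.kal
        ),
        "tether": _tether_energy(pair, p),
        "wca": u_wca,
        "magnetic": u_mag,
    }
    return ForceReport(
        f_outer=f_outer, f_inner=f_inner, f_mnp=f_mnp, torques=torques, energies=energies
    )


def total_energy(state: SimulationState, p: ForceFieldParams) -> dict[str, float]:
    """Per-term potential energies plus their sum (monitoring diagnostic)."""
    rep = total_forces(state, p)
    out = dict(rep.energies)
    out["total"] = sum(out.values())
    return out
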