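"""Langevin dynamics: coupled translational and rotational thermostatted motion.

Every element obeys the underdamped Langevin equation
``m r'' = F - zeta r' + f(t)`` with white-noise forcing satisfying the
fluctuation-dissipation relation ``<f_a(t) f_b(t')> = 2 zeta kT delta_ab
delta(t - t')``. Nanoparticle orientations additionally follow the
rotational analogue driven by the torque ``e x h`` conjugate to the dipolar
plus Zeeman energy; without it dipoles could never align with the field.

The discretisation is the BAOAB splitting of stochastic velocity-Verlet
type: one force evaluation per step, exact Ornstein-Uhlenbeck treatment of
the friction/noise ("O") substep, and second-order-accurate configurational
sampling. Blob frictions follow the Stokes law scaling, i.e. proportional
to element diameter, referenced to the nanoparticle friction ``zeta_t``.

Trajectories are deterministic functions of (state, RNG stream): noise is
drawn per step in a fixed order from the Philox counter-based generator
carried by the state, so a run can be split, checkpointed and resumed with
bitwise-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams, total_forces
from .state import SimulationState

__all__ = [
    "IntegratorConfig",
    "stokes_translational_friction",
    "stokes_rotational_friction",
    "langevin_step",
    "kinetic_temperature",
    "run",
    "integrate_particles",
]


@dataclass(frozen=True)
class IntegratorConfig:
    """Time step, masses, frictions and temperature, all in reduced units.

    ``zeta_t`` is the translational friction of one nanoparticle (Stokes
    ``3 pi a eta`` in physical units); blobs get ``zeta_t`` scaled by their
    diameter ratio. ``zeta_r`` is the rotational friction (Stokes
    ``pi eta a^3``). Defaults satisfy ``dt << m / zeta`` and keep the WCA
    wall stable at kT = 1.
    """

    dt: float = 0.005
    mass: float = 1.0
    inertia: float = 1.0
    zeta_t: float = 1.0
    zeta_r: float = 1.0
    kT: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not (self.mass > 0 and self.inertia > 0):
            raise ValueError("mass and inertia must be > 0")
        if not (self.zeta_t > 0 and self.zeta_r > 0):
            raise ValueError("frictions must be > 0")
        if self.kT < 0:
            raise ValueError("kT must be >= 0")


def stokes_translational_friction(a: float, eta: float) -> float:
    """Stokes drag ``zeta = 3 pi a eta`` for a sphere of diameter ``a``."""
    return 3.0 * math.pi * a * eta


def stokes_rotational_friction(a: float, eta: float) -> float:
    """Stokes rotational drag ``zeta_r = pi eta a^3`` for a sphere of diameter ``a``."""
    return math.pi * eta * a**3


# ---------------------------------------------------------------------------
# packing between the object state and flat kernel arrays


class _Packed:
    """Flat struct-of-arrays view of a SimulationState for the kernels.

    Element order: outer-shell blobs, inner-shell blobs, nanoparticles.
    Topology (edges, triangles, tethers, WCA exclusions) is static per run.
    """

    def __init__(self, state: SimulationState, cfg: IntegratorConfig):
        pair, ens = state.pair, state.ensemble
        n = pair.outer.n_nodes
        m = ens.n_particles
        self.n_blob = 2 * n
        self.n_mnp = m
        self.pos = np.vstack([pair.outer.positions, pair.inner.positions, ens.positions])
        self.vel = np.vstack([pair.outer.velocities, pair.inner.velocities, ens.velocities])
        self.ori = np.array(ens.orientations, dtype=float, copy=True)
        self.angvel = np.array(ens.angular_velocities, dtype=float, copy=True)
        self.diam = np.concatenate(
            [
                np.full(n, pair.outer.blob_diameter),
                np.full(n, pair.inner.blob_diameter),
                np.full(m, ens.diameter),
            ]
        )
        self.edges = np.vstack([pair.outer.edges, pair.inner.edges + n]).astype(np.int64)
        self.r0e = np.concatenate([pair.outer.r0_edge, pair.inner.r0_edge])
        self.tris = np.vstack([pair.outer.triangles, pair.inner.triangles + n]).astype(
            np.int64
        )
        self.s0 = np.concatenate([pair.outer.S0_tri, pair.inner.S0_tri])
        self.teth = np.column_stack(
            [np.arange(n, dtype=np.int64), pair.correspondence.astype(np.int64) + n]
        )
        self.r0t = np.asarray(pair.r0_tether, dtype=float)
        p = len(self.pos)
        self.excl_keys = np.sort(self.edges[:, 0] * p + self.edges[:, 1])
        cap = max(64 * p, 4096)
        self.nb_i = np.empty(cap, dtype=np.int64)
        self.nb_j = np.empty(cap, dtype=np.int64)
        self.nb_state = np.zeros(1, dtype=np.int64)
        self.pos_ref = np.zeros_like(self.pos)
        self.forces = np.zeros_like(self.pos)
        self.torques = np.zeros((m, 3))
        # per-element O-step coefficients (friction scales with diameter)
        ref = ens.diameter if ens.diameter > 0 else 1.0
        zeta = cfg.zeta_t * self.diam / ref
        c1 = np.exp(-zeta * cfg.dt / cfg.mass)
        self.c1t = c1
        self.c2t = np.sqrt(cfg.kT * (1.0 - c1**2) / cfg.mass)
        c1r = math.exp(-cfg.zeta_r * cfg.dt / cfg.inertia)
        self.c1r = c1r
        self.c2r = math.sqrt(cfg.kT * (1.0 - c1r**2) / cfg.inertia)

    def grow_neighbor_buffers(self) -> None:
        cap = 2 * len(self.nb_i)
        self.nb_i = np.empty(cap, dtype=np.int64)
        self.nb_j = np.empty(cap, dtype=np.int64)

    def sync_to_state(self, state: SimulationState) -> None:
        n = state.pair.outer.n_nodes
        state.pair.outer.positions[:] = self.pos[:n]
        state.pair.inner.positions[:] = self.pos[n : 2 * n]
        state.pair.outer.velocities[:] = self.vel[:n]
        state.pair.inner.velocities[:] = self.vel[n : 2 * n]
        if self.n_mnp:
            state.ensemble.positions[:] = self.pos[2 * n :]
            state.ensemble.velocities[:] = self.vel[2 * n :]
            state.ensemble.orientations[:] = self.ori
            state.ensemble.angular_velocities[:] = self.angvel


# ---------------------------------------------------------------------------
# reference single step (numpy)


def langevin_step(
    state: SimulationState, p: ForceFieldParams, cfg: IntegratorConfig
) -> SimulationState:
    """One BAOAB step using the numpy reference forces; mutates and returns state.

    This is the readable reference path; :func:`run` advances the same
    dynamics through the compiled kernels.
    """
    rep = total_forces(state, p)
    if not (
        np.all(np.isfinite(rep.f_outer))
        and np.all(np.isfinite(rep.f_inner))
        and np.all(np.isfinite(rep.f_mnp))
    ):
        raise FloatingPointError("non-finite force input to the integrator")
    packed = _Packed(state, cfg)
    packed.forces[: packed.n_blob // 2] = rep.f_outer
    packed.forces[packed.n_blob // 2 : packed.n_blob] = rep.f_inner
    packed.forces[packed.n_blob :] = rep.f_mnp
    packed.torques[:] = rep.torques
    noise_t = state.rng.standard_normal((1, len(packed.pos), 3))
    noise_r = state.rng.standard_normal((1, packed.n_mnp, 3))

    half = 0.5 * cfg.dt
    packed.vel += half * packed.forces / cfg.mass
    packed.angvel += half * packed.torques / cfg.inertia
    packed.pos += half * packed.vel
    _kernels._rotate_orientations(packed.ori, packed.angvel, half)
    packed.vel = packed.c1t[:, None] * packed.vel + packed.c2t[:, None] * noise_t[0]
    packed.angvel = packed.c1r * packed.angvel + packed.c2r * noise_r[0]
    packed.pos += half * packed.vel
    _kernels._rotate_orientations(packed.ori, packed.angvel, half)
    packed.sync_to_state(state)
    rep = total_forces(state, p)
    packed.vel += half * np.vstack([rep.f_outer, rep.f_inner, rep.f_mnp]) / cfg.mass
    packed.angvel += half * rep.torques / cfg.inertia
    packed.sync_to_state(state)
    state.time += cfg.dt
    state.step += 1
    return state


def kinetic_temperature(state: SimulationState, mass: float = 1.0) -> float:
    """Instantaneous kinetic temperature: ``m <v^2> / 3`` over all elements (kT units)."""
    vels = [
        state.pair.outer.velocities,
        state.pair.inner.velocities,
        state.ensemble.velocities,
    ]
    v = np.vstack([x for x in vels if len(x)])
    if v.size == 0:
        raise ValueError("empty state has no kinetic temperature")
    return float(mass * np.mean(np.sum(v * v, axis=1)) / 3.0)


# ---------------------------------------------------------------------------
# the chunked production driver


def run(
    state: SimulationState,
    n_steps: int,
    ff: ForceFieldParams,
    cfg: IntegratorConfig,
    callbacks: Sequence[Callable[[SimulationState], None]] = (),
    observe_stride: int = 0,
) -> SimulationState:
    """Advance ``n_steps`` Langevin steps through the compiled kernels.

    ``callbacks`` are invoked with the synchronised state every
    ``observe_stride`` steps (and once after the final step). The RNG
    stream is consumed one step at a time, so ``run(a); run(b)`` is
    bitwise identical to ``run(a + b)``.
    """
    if n_steps == 0:
        return state
    packed = _Packed(state, cfg)
    lam_a3 = state.ensemble.lambda_dd * state.ensemble.diameter**3
    fvec = state.field_vector
    stride = observe_stride if observe_stride > 0 else n_steps
    done = 0
    while done < n_steps:
        todo = min(stride, n_steps - done)
        noise_t = np.empty((todo, len(packed.pos), 3))
        noise_r = np.empty((todo, packed.n_mnp, 3))
        for s in range(todo):  # per-step draws keep chunking out of the stream
            noise_t[s] = state.rng.standard_normal((len(packed.pos), 3))
            noise_r[s] = state.rng.standard_normal((packed.n_mnp, 3))
        while True:
            rc = _kernels.run_chunk(
                packed.pos, packed.vel, packed.ori, packed.angvel,
                packed.forces, packed.torques, noise_t, noise_r,
                cfg.dt, cfg.mass, cfg.inertia,
                packed.c1t, packed.c2t, packed.c1r, packed.c2r,
                packed.diam, packed.edges, packed.r0e, packed.tris, packed.s0,
                packed.teth, packed.r0t, packed.excl_keys,
                packed.nb_i, packed.nb_j, packed.nb_state, packed.pos_ref,
                ff.ks, ff.kal, ff.kh, ff.eps, lam_a3,
                fvec[0], fvec[1], fvec[2],
                state.magnetics_on, packed.n_mnp,
            )
            if rc == -1:  # entry overflow: nothing mutated, safe to retry
                packed.grow_neighbor_buffers()
                continue
            if rc == -2:
                packed.sync_to_state(state)
                raise FloatingPointError(
                    f"non-finite forces at step {state.step + done}; "
                    "state synchronised for post-mortem"
                )
            if rc == -3:
                raise RuntimeError(
                    "neighbour list overflowed mid-chunk despite headroom; "
                    "system density changed implausibly fast"
                )
            break
        done += todo
        state.time += todo * cfg.dt
        state.step += todo
        packed.sync_to_state(state)
        for cb in callbacks:
            cb(state)
    return state


# ---------------------------------------------------------------------------
# generic point-particle integrator (external force fields)


def integrate_particles(
    force_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    v0: np.ndarray,
    n_steps: int,
    cfg: IntegratorConfig,
    rng: np.random.Generator,
    record_stride: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """BAOAB Langevin integration of independent point particles in an
    external force field (vectorised numpy; no excluded volume).

    Used for thermostat validation (equipartition, harmonic-well sampling,
    free diffusion) and handy for quick estimates. Returns final positions,
    velocities and the recorded position frames.
    """
    x = np.array(x0, dtype=float, copy=True)
    v = np.array(v0, dtype=float, copy=True)
    half = 0.5 * cfg.dt
    c1 = math.exp(-cfg.zeta_t * cfg.dt / cfg.mass)
    c2 = math.sqrt(cfg.kT * (1.0 - c1 * c1) / cfg.mass)
    frames: list[np.ndarray] = []
    f = force_fn(x)
    for s in range(n_steps):
        v += half * f / cfg.mass
        x += half * v
        v = c1 * v + c2 * rng.standard_normal(v.shape)
        x += half * v
        f = force_fn(x)
        v += half * f / cfg.mass
        if record_stride and (s + 1) % record_stride == 0:
            frames.append(x.copy())
    return x, v, frames
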