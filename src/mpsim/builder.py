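"""Assembly of the full polymersome and the preparation/magnetisation protocol.

The protocol mirrors quasi-static magnetisation of a freshly prepared
vesicle: (1) build the two tethered shells and load the intra-membrane
layer with nanoparticles at the target volume fraction; (2) thermalise with
every interaction except the magnetic ones; (3) switch on dipole-dipole
coupling at zero field and relax to the ground state (energy plateau);
(4) ramp the applied field up through a non-decreasing schedule of Langevin
arguments xi, equilibrating and measuring at each level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import IntegratorConfig, run
from .forcefield import ForceFieldParams, total_energy
from .mesh import ShellPair, layer_thickness, make_sphere_mesh, pair_shells
from .observables import ObservableSeries, aspect_ratio, cluster_stats, magnetization
from .state import NanoparticleEnsemble, SimulationState

log = logging.getLogger("mpsim")

__all__ = [
    "SystemSpec",
    "FieldProtocol",
    "EquilibrationResult",
    "default_field_protocol",
    "n_particles_from_phi",
    "place_nanoparticles",
    "assemble_system",
    "equilibrate",
    "magnetise",
]


@dataclass(frozen=True)
class SystemSpec:
    """Geometry, loading and couplings of one polymersome, reduced units.

    Default geometry: outer/inner shell diameters 24/16, blob diameters
    3.1/2, particle diameter 1.2 — an accessible layer of width 1.45, just
    over one particle diameter, so the magnetic phase forms a monolayer.
    """

    Dout: float = 24.0
    Din: float = 16.0
    dout: float = 3.1
    din: float = 2.0
    a_red: float = 1.2
    phi: float = 0.055  # volume fraction of magnetic phase in the layer
    lambda_dd: float = 1.0
    n_nodes: int = 393
    max_particles: int = 393
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)

    def __post_init__(self) -> None:
        ell = layer_thickness(self.Dout, self.dout, self.Din, self.din)
        if ell < self.a_red:
            raise ValueError(
                f"layer thickness {ell} cannot accommodate a particle monolayer "
                f"of diameter {self.a_red}"
            )
        if not 0.0 <= self.phi <= 0.3:
            raise ValueError(f"volume fraction out of supported range: {self.phi}")
        if self.lambda_dd < 0:
            raise ValueError("lambda_dd must be >= 0")

    @property
    def layer(self) -> float:
        return layer_thickness(self.Dout, self.dout, self.Din, self.din)

    @property
    def r_band(self) -> tuple[float, float]:
        """Admissible radial band for particle centres."""
        return (
            self.Din / 2 + self.din / 2 + self.a_red / 2,
            self.Dout / 2 - self.dout / 2 - self.a_red / 2,
        )


@dataclass(frozen=True)
class FieldProtocol:
    """Quasi-static field ramp: (xi, equilibration steps, measurement steps) levels."""

    levels: tuple[tuple[float, int, int], ...]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    measure_stride: int = 250

    def __post_init__(self) -> None:
        xis = [lvl[0] for lvl in self.levels]
        if any(b < a for a, b in zip(xis, xis[1:])):
            raise ValueError("xi schedule must be non-decreasing (quasi-static ramp)")
        if any(x < 0 for x in xis):
            raise ValueError("xi must be >= 0")


def default_field_protocol(n_equil: int = 20000, n_measure: int = 10000) -> FieldProtocol:
    """The default ramp covering the studied field range up to xi = 10."""
    xis = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0)
    return FieldProtocol(levels=tuple((x, n_equil, n_measure) for x in xis))


def n_particles_from_phi(spec: SystemSpec) -> int:
    """Particle count from the layer volume and target volume fraction.

    ``N = round(phi * V_layer / v_p)`` with the layer bounded by the
    blob-centre surfaces offset by the blob radii:
    ``V_layer = (4 pi / 3) [(Dout/2 - dout/2)^3 - (Din/2 + din/2)^3]``.
    105 / 210 particles for the default geometry at phi = 5.5 / 11 vol.%.
    """
    r_out = spec.Dout / 2 - spec.dout / 2
    r_in = spec.Din / 2 + spec.din / 2
    v_layer = 4.0 * math.pi / 3.0 * (r_out**3 - r_in**3)
    v_p = math.pi / 6.0 * spec.a_red**3
    n = int(round(spec.phi * v_layer / v_p))
    if n > spec.max_particles:
        raise ValueError(
            f"phi={spec.phi} requires {n} particles, exceeding the cap of "
            f"{spec.max_particles} elements per species"
        )
    return n


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def place_nanoparticles(
    spec: SystemSpec, pair: ShellPair, rng: np.random.Generator
) -> NanoparticleEnsemble:
    """Random sequential insertion of the nanoparticle monolayer.

    Uniform solid angle, uniform admissible radius; a placement is rejected
    when closer than one particle diameter to an existing particle or than
    the WCA contact distance to any blob. Deterministic for a given RNG
    stream.
    """
    n = n_particles_from_phi(spec)
    lo, hi = spec.r_band
    blob_pos = np.vstack([pair.outer.positions, pair.inner.positions])
    blob_contact = np.concatenate(
        [
            np.full(pair.outer.n_nodes, (spec.a_red + pair.outer.blob_diameter) / 2),
            np.full(pair.inner.n_nodes, (spec.a_red + pair.inner.blob_diameter) / 2),
        ]
    )
    placed = np.empty((n, 3))
    count = 0
    max_attempts = 2000 * max(n, 1)
    for _ in range(max_attempts):
        if count == n:
            break
        u = _random_unit_vectors(rng, 1)[0]
        r = rng.uniform(lo, hi)
        cand = r * u
        if count and np.min(np.linalg.norm(placed[:count] - cand, axis=1)) < spec.a_red:
            continue
        if np.any(np.linalg.norm(blob_pos - cand, axis=1) < blob_contact):
            continue
        placed[count] = cand
        count += 1
    if count < n:
        raise RuntimeError(
            f"packing failure: placed {count}/{n} particles in {max_attempts} attempts"
        )
    return NanoparticleEnsemble(
        positions=placed,
        orientations=_random_unit_vectors(rng, n),
        diameter=spec.a_red,
        lambda_dd=spec.lambda_dd,
    )


def assemble_system(spec: SystemSpec, seed: int = 0) -> SimulationState:
    """Build shells, tether them, load particles; field off, magnetics on."""
    outer = make_sphere_mesh(spec.n_nodes, spec.Dout, spec.dout)
    inner = make_sphere_mesh(spec.n_nodes, spec.Din, spec.din)
    pair = pair_shells(outer, inner)
    rng = np.random.Generator(np.random.Philox(seed))
    ens = place_nanoparticles(spec, pair, rng)
    return SimulationState(pair=pair, ensemble=ens, field_xi=0.0, rng=rng)


@dataclass
class EquilibrationResult:
    state: SimulationState
    converged: bool
    energy_history: list[float]


def equilibrate(
    state: SimulationState,
    spec: SystemSpec,
    n_pre: int = 10000,
    window: int = 10000,
    tol: float = 1e-3,
    max_windows: int = 20,
) -> EquilibrationResult:
    """Two-stage thermalisation to the zero-field ground state.

    Stage A runs ``n_pre`` steps with the magnetic interactions disabled
    (sterics and elasticity only); stage B enables dipolar coupling at zero
    field and runs in windows until the trailing-window mean total energy
    changes by less than ``tol`` (relative), or the window budget is spent
    (flagged, not fatal).
    """
    ff, cfg = spec.forcefield, spec.integrator
    state.field_xi = 0.0
    state.magnetics_on = False
    run(state, n_pre, ff, cfg)
    state.magnetics_on = True
    history: list[float] = []
    prev_mean = None
    converged = False
    stride = max(window // 20, 1)
    for _ in range(max_windows):
        samples = []

        def _sample(s: SimulationState) -> None:
            samples.append(total_energy(s, ff)["total"])

        run(state, window, ff, cfg, callbacks=[_sample], observe_stride=stride)
        mean = float(np.mean(samples))
        history.append(mean)
        breakdown = total_energy(state, ff)
        log.info(
            "equilibrate window at step %d: %s",
            state.step,
            {k: round(v, 2) for k, v in breakdown.items()},
        )
        if prev_mean is not None:
            scale = max(abs(prev_mean), abs(mean), 1.0)
            if abs(mean - prev_mean) / scale < tol:
                converged = True
                break
        prev_mean = mean
    return EquilibrationResult(state=state, converged=converged, energy_history=history)


def magnetise(
    state: SimulationState, protocol: FieldProtocol, spec: SystemSpec
) -> ObservableSeries:
    """Quasi-static field ramp from the ground state; one record per xi level.

    At each level the system is equilibrated, then the aspect ratio (both
    estimators), magnetization and cluster statistics are averaged over the
    measurement phase. Independent realisations (different build seeds) can
    be averaged by repeating the whole pipeline; see the CLI presets.
    """
    ff, cfg = spec.forcefield, spec.integrator
    hdir = np.asarray(protocol.direction, dtype=float)
    series = ObservableSeries()
    for xi, n_eq, n_meas in protocol.levels:
        state.field_xi = xi
        state.field_dir = hdir / np.linalg.norm(hdir)
        if n_eq:
            run(state, n_eq, ff, cfg)
        ars, mags, bonded = [], [], []

        def _measure(s: SimulationState) -> None:
            ars.append(aspect_ratio(s.pair.outer.positions, s.field_dir))
            if s.ensemble.n_particles:
                mags.append(magnetization(s.ensemble, s.field_dir))
                bonded.append(cluster_stats(s.ensemble).bonded_fraction)

        run(state, n_meas, ff, cfg, callbacks=[_measure],
            observe_stride=protocol.measure_stride)
        series.append(
            xi=xi,
            aspect_ratio=float(np.mean(ars)),
            aspect_ratio_std=float(np.std(ars)),
            mean_alignment=float(np.mean(mags)) if mags else np.nan,
            bonded_fraction=float(np.mean(bonded)) if bonded else np.nan,
            n_frames=len(ars),
            step=state.step,
        )
    return series
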