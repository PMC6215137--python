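"""In-memory containers for the assembled system.

The integrator advances a :class:`SimulationState`: two tethered shells, the
confined nanoparticle ensemble, the applied field and the RNG stream. All
quantities are in reduced units (kT = 1, particle diameter ``a_red``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import ShellPair

__all__ = ["NanoparticleEnsemble", "SimulationState"]


@dataclass
class NanoparticleEnsemble:
    """Mobile dipolar nanoparticles confined in the intra-membrane layer.

    Each particle carries a permanent point dipole of fixed reduced strength
    (entering through the coupling ``lambda_dd``) along the unit vector
    ``orientations[i]``; particles are translationally and rotationally free.
    """

    positions: np.ndarray  # (M, 3)
    orientations: np.ndarray  # (M, 3) unit vectors
    velocities: np.ndarray = field(default=None)  # type: ignore[assignment]
    angular_velocities: np.ndarray = field(default=None)  # type: ignore[assignment]
    diameter: float = 1.2
    lambda_dd: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        if self.angular_velocities is None:
            self.angular_velocities = np.zeros_like(self.positions)
        if self.n_particles:
            norms = np.linalg.norm(self.orientations, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("dipole orientations must be unit vectors")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def normalize_orientations(self) -> None:
        if self.n_particles:
            self.orientations /= np.linalg.norm(self.orientations, axis=1, keepdims=True)

    @classmethod
    def empty(cls, diameter: float = 1.2, lambda_dd: float = 0.0) -> "NanoparticleEnsemble":
        z = np.zeros((0, 3))
        return cls(positions=z, orientations=z, diameter=diameter, lambda_dd=lambda_dd)


@dataclass
class SimulationState:
    """Everything the integrator advances, plus the RNG stream.

    ``field_xi`` is the reduced Zeeman coupling of the applied field (the
    Langevin argument) and ``field_dir`` its direction; ``magnetics_on``
    gates the dipole-dipole and Zeeman terms so the assembly protocol can
    thermalise sterics first.
    """

    pair: ShellPair
    ensemble: NanoparticleEnsemble
    field_xi: float = 0.0
    field_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    magnetics_on: bool = True
    time: float = 0.0
    step: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.Generator(np.random.Philox(0))
    )

    def __post_init__(self) -> None:
        self.field_dir = np.asarray(self.field_dir, dtype=float)
        n = np.linalg.norm(self.field_dir)
        if n == 0:
            raise ValueError("field direction must be a nonzero vector")
        self.field_dir = self.field_dir / n

    @property
    def field_vector(self) -> np.ndarray:
        """Reduced applied field xi * h_hat (zero while magnetics are off)."""
        if not self.magnetics_on:
            return np.zeros(3)
        return self.field_xi * self.field_dir

    @property
    def n_elements(self) -> int:
        return 2 * self.pair.outer.n_nodes + self.ensemble.n_particles

    def copy(self) -> "SimulationState":
        """Deep copy of all mutable arrays; the RNG stream state is cloned too."""
        import copy as _copy

        return _copy.deepcopy(self)
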