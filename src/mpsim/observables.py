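"""Measured quantities: MSD, shape anisotropy, cluster statistics, magnetization.

The structural observables mirror what one extracts from the simulated
polymersome: the mean-square displacement of the confined nanoparticles at
zero field (free vs chain-hindered diffusion), single-linkage cluster
statistics that detect dipolar chain formation, the elongation of the shell
along the applied field (aspect ratio, 1 for a sphere), the sigmoidal
field-dependence of that elongation, and the mean dipole alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .state import NanoparticleEnsemble

__all__ = [
    "ObservableSeries",
    "ClusterStats",
    "SigmoidFit",
    "msd",
    "msd_linearity_ratio",
    "aspect_ratio",
    "aspect_ratio_slab",
    "cluster_stats",
    "fit_sigmoid",
    "magnetization",
]


@dataclass
class ObservableSeries:
    """Tidy time- or field-indexed record collection (one dict per frame)."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    def __len__(self) -> int:
        return len(self.records)


def msd(trajectory: np.ndarray, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean-square displacement averaged over particles and all time origins.

    ``trajectory`` has shape (frames, particles, 3); returns (lags, msd)
    with ``msd[0] = 0``. Uses every admissible time origin per lag.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 3 or traj.shape[0] < 2:
        raise ValueError("need a (frames >= 2, particles, 3) trajectory")
    n_frames = traj.shape[0]
    if max_lag is None:
        max_lag = n_frames - 1
    max_lag = min(max_lag, n_frames - 1)
    lags = np.arange(max_lag + 1)
    out = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        d = traj[lag:] - traj[:-lag]
        out[lag] = np.mean(np.sum(d * d, axis=2))
    return lags, out


def msd_linearity_ratio(
    lags: np.ndarray, values: np.ndarray, window: tuple[int, int] | None = None
) -> float:
    """Log-log slope of MSD vs lag: ~1 for free diffusion, <1 when hindered, 2 ballistic."""
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (lags > 0) & (values > 0)
    if window is not None:
        mask &= (lags >= window[0]) & (lags <= window[1])
    if mask.sum() < 2:
        raise ValueError("need at least two positive (lag, msd) points in the window")
    slope, _ = np.polyfit(np.log(lags[mask]), np.log(values[mask]), 1)
    return float(slope)


def aspect_ratio(positions: np.ndarray, h_dir: np.ndarray) -> float:
    """Shape elongation along the field from the node-position covariance.

    ``sqrt(var_parallel / gm(var_transverse))``: the variance of the node
    cloud along ``h_dir`` over the geometric mean of the two transverse
    principal variances. Exactly the affine stretch factor for an affinely
    deformed sphere; 1 for an isotropic cloud.
    """
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 4:
        raise ValueError("need at least 4 positions for a shape estimate")
    h = np.asarray(h_dir, dtype=float)
    h = h / np.linalg.norm(h)
    rel = pos - pos.mean(axis=0)
    var_par = float(np.mean((rel @ h) ** 2))
    perp = rel - np.outer(rel @ h, h)
    cov = perp.T @ perp / len(pos)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]  # one eigenvalue ~0 (along h)
    v1, v2 = evals[0], evals[1]
    if v1 <= 0 or v2 <= 0:
        raise ValueError("degenerate (collinear) node set")
    return float(np.sqrt(var_par / np.sqrt(v1 * v2)))


def aspect_ratio_slab(
    positions: np.ndarray,
    h_dir: np.ndarray,
    n_plane: np.ndarray | None = None,
    delta: float = 1.0,
) -> float:
    """Cross-check estimator: 2D covariance ellipse of a central slab.

    Keeps nodes within ``|x . n_plane| < delta`` of the central plane that
    contains ``h_dir``, then returns the ratio of the in-plane ellipse
    semi-axis along the field to the transverse one.
    """
    pos = np.asarray(positions, dtype=float)
    h = np.asarray(h_dir, dtype=float)
    h = h / np.linalg.norm(h)
    if n_plane is None:
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ h) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        n_plane = np.cross(h, trial)
    n_plane = np.asarray(n_plane, dtype=float)
    n_plane = n_plane / np.linalg.norm(n_plane)
    t = np.cross(n_plane, h)  # in-plane transverse axis
    rel = pos - pos.mean(axis=0)
    sel = np.abs(rel @ n_plane) < delta
    if sel.sum() < 4:
        raise ValueError("slab too thin: fewer than 4 nodes selected")
    u, w = rel[sel] @ h, rel[sel] @ t
    var_u, var_w = float(np.mean(u * u)), float(np.mean(w * w))
    if var_u <= 0 or var_w <= 0:
        raise ValueError("degenerate slab configuration")
    return float(np.sqrt(var_u / var_w))


@dataclass(frozen=True)
class ClusterStats:
    """Cluster-size histogram and summary aggregation measures."""

    sizes: np.ndarray  # cluster size per cluster
    histogram: dict[int, int]  # size -> count of clusters
    largest: int
    bonded_fraction: float  # fraction of particles in clusters of size >= 2

    @property
    def n_particles(self) -> int:
        return int(self.sizes.sum())


def cluster_stats(
    ensemble_or_positions, diameter: float | None = None, bond_factor: float = 1.3
) -> ClusterStats:
    """Single-linkage cluster statistics with bond criterion ``r < bond_factor * a``.

    Two particles are bonded when their centre distance is below 1.3 particle
    diameters (the common dipolar-fluid convention); clusters are the
    connected components of the bond graph, i.e. single-linkage clusters at
    that threshold.
    """
    if isinstance(ensemble_or_positions, NanoparticleEnsemble):
        pos = ensemble_or_positions.positions
        a = ensemble_or_positions.diameter
    else:
        pos = np.asarray(ensemble_or_positions, dtype=float)
        if diameter is None:
            raise ValueError("diameter required when passing bare positions")
        a = diameter
    m = len(pos)
    if m == 0:
        return ClusterStats(np.zeros(0, dtype=int), {}, 0, 0.0)
    if m == 1:
        return ClusterStats(np.ones(1, dtype=int), {1: 1}, 1, 0.0)
    adj = squareform(pdist(pos)) < bond_factor * a
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels)
    hist: dict[int, int] = {}
    for s in sizes:
        hist[int(s)] = hist.get(int(s), 0) + 1
    bonded = float(sizes[sizes >= 2].sum()) / m
    return ClusterStats(
        sizes=np.sort(sizes)[::-1], histogram=hist, largest=int(sizes.max()),
        bonded_fraction=bonded,
    )


@dataclass(frozen=True)
class SigmoidFit:
    """4-parameter logistic fit of the aspect-ratio vs field curve."""

    ar0: float
    ar_inf: float
    xi_half: float
    width: float
    residual_norm: float
    degenerate: bool  # flat data / unconstrained width
    converged: bool

    def __call__(self, xi) -> np.ndarray:
        return _logistic(np.asarray(xi, dtype=float), self.ar0, self.ar_inf,
                         self.xi_half, self.width)


def _logistic(xi, ar0, ar_inf, xi_half, width):
    return ar0 + (ar_inf - ar0) / (1.0 + np.exp(-(xi - xi_half) / width))


def fit_sigmoid(xi_values: np.ndarray, ar_values: np.ndarray) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit ``AR(xi)``.

    Returns the fitted plateau values, half-saturation field and width plus
    the residual norm; constant data is flagged degenerate rather than
    raising.
    """
    x = np.asarray(xi_values, dtype=float)
    y = np.asarray(ar_values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points for a 4-parameter fit")
    span = y.max() - y.min()
    if span < 1e-12 * max(1.0, abs(y.mean())):
        return SigmoidFit(float(y.mean()), float(y.mean()), float(np.median(x)),
                          float(np.ptp(x) / 4 + 1e-12), 0.0, True, True)
    p0 = [y[np.argmin(x)], y[np.argmax(x)], float(np.median(x)), max(np.ptp(x) / 6, 1e-3)]
    try:
        popt, _ = curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return SigmoidFit(*p0, residual_norm=float(np.linalg.norm(y - _logistic(x, *p0))),
                          degenerate=False, converged=False)
    resid = float(np.linalg.norm(y - _logistic(x, *popt)))
    degenerate = abs(popt[1] - popt[0]) < 1e-9 or abs(popt[3]) > 100 * max(np.ptp(x), 1.0)
    return SigmoidFit(*map(float, popt), residual_norm=resid, degenerate=degenerate,
                      converged=True)


def magnetization(ensemble_or_orientations, h_dir: np.ndarray) -> float:
    """Mean reduced magnetization per particle, ``<e_i . h_hat>`` in [-1, 1]."""
    if isinstance(ensemble_or_orientations, NanoparticleEnsemble):
        e = ensemble_or_orientations.orientations
    else:
        e = np.atleast_2d(np.asarray(ensemble_or_orientations, dtype=float))
    if len(e) == 0:
        raise ValueError("empty ensemble has no magnetization")
    h = np.asarray(h_dir, dtype=float)
    h = h / np.linalg.norm(h)
    return float(np.mean(e @ h))
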