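"""Structural analysis of 2D configurations: g(r), Ψ6 and neighbor counts.

The radial distribution function is g(r) = N(r)/(2π n r Δr) per central
particle, with N(r) the pair count in a shell of width Δr and n the surface
number density.  Ψ6 is the six-fold bond-orientational order parameter,
Ψ6^i = (1/N_b) Σ_j exp(i·6θ_ij) over the N_b neighbors of particle i: 1 on
a perfect triangular lattice, 0 for square or uncorrelated arrangements.
Neighbors are particles closer than a cutoff derived from the g(r) extrema
(diameter plus half the first-peak-to-first-minimum distance).

Periodic inputs use the minimum-image convention; non-periodic
(experimental-style) inputs exclude a guard region near the box edges so
that every counted shell is complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from brushpack.mc import Configuration2D

__all__ = [
    "RadialDistribution",
    "OrderMetrics",
    "PeakResult",
    "radial_distribution",
    "first_peak",
    "neighbor_cutoff",
    "psi6",
    "mean_neighbors",
    "analyze_configurations",
]


@dataclass(frozen=True)
class RadialDistribution:
    """Averaged g(r) histogram."""

    bin_centers: np.ndarray
    g: np.ndarray
    dr: float
    n_density: float
    n_configs: int


@dataclass(frozen=True)
class PeakResult:
    """Location/height of a g(r) extremum; ``found`` is False when no
    peak rises above 1 (e.g. the salt-screened fluid)."""

    r: float | None
    g: float | None
    found: bool


@dataclass(frozen=True)
class OrderMetrics:
    """Summary structural observables of one state point."""

    r_p: float | None
    g_p: float | None
    neighbor_cutoff: float | None
    mean_neighbors: float
    psi6_per_particle: np.ndarray
    mean_psi6: float


# --------------------------------------------------------------------------
# pair distances
# --------------------------------------------------------------------------


def _pair_displacements(cfg: Configuration2D) -> np.ndarray:
    """All i<j displacement vectors, minimum-image if periodic."""
    pos = cfg.positions
    d = pos[:, None, :] - pos[None, :, :]
    if cfg.periodic:
        box = np.asarray(cfg.box)
        d -= box * np.round(d / box)
    iu = np.triu_indices(cfg.n, k=1)
    return d[iu]


def _neighbor_matrix(cfg: Configuration2D, cutoff: float) -> np.ndarray:
    pos = cfg.positions
    d = pos[:, None, :] - pos[None, :, :]
    if cfg.periodic:
        box = np.asarray(cfg.box)
        d -= box * np.round(d / box)
    r2 = (d**2).sum(axis=-1)
    np.fill_diagonal(r2, np.inf)
    return r2 <= cutoff**2


def radial_distribution(configs: Sequence[Configuration2D], dr: float = 0.02,
                        r_max: float | None = None) -> RadialDistribution:
    """g(r) averaged over configurations.

    Periodic inputs count all minimum-image pairs; non-periodic inputs use
    only central particles at least ``r_max`` from every edge (guard
    region) so no shell is truncated.
    """
    if len(configs) == 0:
        raise ValueError("need at least one configuration")
    if dr <= 0:
        raise ValueError("dr must be positive")
    box = np.asarray(configs[0].box, dtype=float)
    half_min_side = 0.5 * box.min()
    if r_max is None:
        r_max = half_min_side
    if configs[0].periodic and r_max > half_min_side * (1 + 1e-9):
        raise ValueError("r_max exceeds half the smallest box side")

    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    n_centers_total = 0.0
    density_sum = 0.0
    for cfg in configs:
        area = cfg.box[0] * cfg.box[1]
        density_sum += cfg.n / area
        if cfg.periodic:
            r = np.linalg.norm(_pair_displacements(cfg), axis=1)
            counts += 2.0 * np.histogram(r, bins=edges)[0]  # both directions
            n_centers_total += cfg.n
        else:
            pos = cfg.positions
            interior = (
                (pos[:, 0] >= r_max) & (pos[:, 0] <= cfg.box[0] - r_max)
                & (pos[:, 1] >= r_max) & (pos[:, 1] <= cfg.box[1] - r_max)
            )
            centers = pos[interior]
            if len(centers) == 0:
                continue
            d = centers[:, None, :] - pos[None, :, :]
            r = np.sqrt((d**2).sum(axis=-1)).ravel()
            r = r[r > 1e-12]  # drop self-pairs
            counts += np.histogram(r, bins=edges)[0]
            n_centers_total += interior.sum()
    if n_centers_total == 0:
        raise ValueError("no central particles available (guard region too wide?)")
    n_density = density_sum / len(configs)
    centers_r = 0.5 * (edges[:-1] + edges[1:])
    shell = 2.0 * np.pi * centers_r * dr
    g = counts / (n_centers_total * shell * n_density)
    return RadialDistribution(
        bin_centers=centers_r, g=g, dr=dr, n_density=n_density,
        n_configs=len(configs),
    )


# --------------------------------------------------------------------------
# peak analysis
# --------------------------------------------------------------------------


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (falls back to the
    bin itself at the array ends or for degenerate curvature)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-300:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    xv = x[i] + delta * (x[1] - x[0])
    yv = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return float(xv), float(yv)


def first_peak(grd: RadialDistribution, min_height: float = 1.0) -> PeakResult:
    """Position and height of the first local maximum of g(r) above
    ``min_height``, with parabolic sub-bin refinement.  Returns a
    ``found=False`` result when no such peak exists."""
    g = grd.g
    for i in range(1, len(g) - 1):
        is_max = g[i] >= g[i - 1] and g[i] >= g[i + 1] and (
            g[i] > g[i - 1] or g[i] > g[i + 1]
        )
        if is_max and g[i] > min_height:
            r_p, g_p = _parabolic_refine(grd.bin_centers, g, i)
            return PeakResult(r=r_p, g=g_p, found=True)
    return PeakResult(r=None, g=None, found=False)


def _smooth3(y: np.ndarray) -> np.ndarray:
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def neighbor_cutoff(grd: RadialDistribution, sigma: float) -> float:
    """Neighbor distance σ + (r_min − r_peak)/2 from the g(r) extrema.

    ``sigma`` is the current steric diameter.  The first-shell minimum is
    located as the lowest point of the 3-bin-smoothed g(r) within one
    diameter beyond the first peak — in weakly structured fluids the
    minimum is shallow, so a windowed argmin is far more stable against
    bin noise than pointwise extremum detection.  The minimum must be an
    interior point of the window (a curve that still decreases at the
    window edge has no identifiable first shell).
    """
    peak = first_peak(grd)
    if not peak.found:
        raise ValueError("no first peak identifiable in g(r)")
    g_s = _smooth3(grd.g)
    i_peak = int(np.argmin(np.abs(grd.bin_centers - peak.r)))
    i_hi = min(i_peak + 1 + int(np.ceil(sigma / grd.dr)), len(g_s))
    if i_hi - i_peak < 3:
        raise ValueError("g(r) range too short beyond the first peak")
    window = g_s[i_peak + 1:i_hi]
    i_min = i_peak + 1 + int(np.argmin(window))
    if i_min >= i_hi - 1 and g_s[i_min] < g_s[i_min - 1]:
        raise ValueError("no first minimum identifiable within one diameter "
                         "of the first peak")
    r_min, _ = _parabolic_refine(grd.bin_centers, -g_s, i_min)
    return sigma + 0.5 * (r_min - peak.r)


# --------------------------------------------------------------------------
# orientational order and coordination
# --------------------------------------------------------------------------


def psi6(cfg: Configuration2D, cutoff: float,
         reduce: str = "magnitude") -> tuple[np.ndarray, float]:
    """Per-particle |Ψ6^i| and their average.

    Ψ6^i = (1/N_b) Σ_j exp(i·6θ_ij) over neighbors within ``cutoff``; a
    particle with no neighbors scores 0.  ``reduce`` selects the sample
    average: ``"magnitude"`` (mean of |Ψ6^i|, default) or ``"complex"``
    (modulus of the mean complex Ψ6^i).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = cfg.positions
    d = pos[:, None, :] - pos[None, :, :]
    if cfg.periodic:
        box = np.asarray(cfg.box)
        d -= box * np.round(d / box)
    r2 = (d**2).sum(axis=-1)
    np.fill_diagonal(r2, np.inf)
    nbr = r2 <= cutoff**2
    theta = np.arctan2(d[..., 1], d[..., 0])
    phase = np.exp(6j * theta)
    n_b = nbr.sum(axis=1)
    psi = np.zeros(cfg.n, dtype=complex)
    has = n_b > 0
    psi[has] = (phase * nbr).sum(axis=1)[has] / n_b[has]
    mags = np.abs(psi)
    if reduce == "magnitude":
        mean = float(mags.mean())
    elif reduce == "complex":
        mean = float(np.abs(psi.mean()))
    else:
        raise ValueError("reduce must be 'magnitude' or 'complex'")
    return mags, mean


def mean_neighbors(cfg: Configuration2D, cutoff: float) -> float:
    """Average number of neighbors per particle within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return float(_neighbor_matrix(cfg, cutoff).sum(axis=1).mean())


def analyze_configurations(configs: Sequence[Configuration2D], sigma: float,
                           dr: float = 0.02,
                           r_max: float | None = None) -> OrderMetrics:
    """Full structural pipeline: g(r) → first peak → neighbor cutoff →
    Ψ6 and coordination, averaged over the configurations."""
    grd = radial_distribution(configs, dr=dr, r_max=r_max)
    peak = first_peak(grd)
    if peak.found:
        try:
            cutoff = neighbor_cutoff(grd, sigma)
        except ValueError:
            cutoff = None
    else:
        cutoff = None
    if cutoff is None or cutoff <= 0:
        zeros = np.zeros(sum(c.n for c in configs))
        return OrderMetrics(
            r_p=peak.r, g_p=peak.g, neighbor_cutoff=None,
            mean_neighbors=0.0, psi6_per_particle=zeros, mean_psi6=0.0,
        )
    mags_all, psi_means, nb_means = [], [], []
    for cfg in configs:
        mags, mean = psi6(cfg, cutoff)
        mags_all.append(mags)
        psi_means.append(mean)
        nb_means.append(mean_neighbors(cfg, cutoff))
    return OrderMetrics(
        r_p=peak.r,
        g_p=peak.g,
        neighbor_cutoff=cutoff,
        mean_neighbors=float(np.mean(nb_means)),
        psi6_per_particle=np.concatenate(mags_all),
        mean_psi6=float(np.mean(psi_means)),
    )
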