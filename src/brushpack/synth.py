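"""Seeded generators for reference configurations and trajectories.

These produce the idealized structures against which the analysis modules
are validated: triangular (hexagonal) crystals with Ψ6 = 1 and g(r) peak
ratios 1:√3:2, Poisson (ideal-gas) fluids with g ≡ 1, chainlike aggregates
with mean coordination ≈ 2 emulating the low-packing-fraction morphology
of attractive brushes, and 2D Brownian trajectories with optional linear
stage drift for the MSD pipeline.  Every generator is fully determined by
its seed and keeps coordinates inside the requested box.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from brushpack.cell_model import BrushGeometry
from brushpack.dynamics import TrackSet
from brushpack.mc import Configuration2D

__all__ = [
    "gen_hexagonal",
    "gen_poisson",
    "gen_chains",
    "gen_brownian_tracks",
    "miniature_brush_params",
    "experimental_brush_params",
]


def gen_hexagonal(spacing: float, box: Sequence[float]) -> Configuration2D:
    """Triangular lattice filling the box, nearest-neighbor distance
    ``spacing``.

    A warning is emitted when the box is not commensurate with the lattice
    (row spacing √3/2·spacing), in which case edge rows/columns wrap
    imperfectly under periodic boundaries.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    Lx, Ly = float(box[0]), float(box[1])
    row_h = spacing * np.sqrt(3.0) / 2.0
    n_cols = int(round(Lx / spacing))
    n_rows = int(round(Ly / row_h))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("box too small for a single lattice cell")
    if (abs(n_cols * spacing - Lx) > 1e-9 * Lx
            or abs(n_rows * row_h - Ly) > 1e-9 * Ly or n_rows % 2):
        warnings.warn(
            "box is not commensurate with the triangular lattice; "
            "periodic images will be strained"
        )
    pts = []
    for row in range(n_rows):
        xoff = 0.5 * spacing if row % 2 else 0.0
        for col in range(n_cols):
            pts.append(((col * spacing + xoff) % Lx, row * row_h))
    return Configuration2D(np.asarray(pts), (Lx, Ly))


def gen_poisson(n: int, box: Sequence[float],
                seed: int | np.random.Generator = 0) -> Configuration2D:
    """``n`` uniform independent points: the g = 1, low-Ψ6 reference."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2)) * np.asarray(box, dtype=float)
    return Configuration2D(pos, (float(box[0]), float(box[1])))


def gen_chains(n_chains: int, box: Sequence[float], bond_distance: float = 1.0,
               seed: int | np.random.Generator = 0,
               chain_length_distribution: Callable[[np.random.Generator], int] | None = None,
               singles_fraction: float = 0.2, turn_angle: float = np.pi / 6,
               min_sep_factor: float = 0.9,
               max_retries: int = 200) -> Configuration2D:
    """Chainlike aggregate configuration: self-avoiding strings of touching
    particles plus isolated singles.

    Chains are gently curved random walks (bond-angle increments uniform in
    ±``turn_angle``) with bonds of length ``bond_distance``; chain lengths
    default to a geometric distribution of mean 5 (min 2), and a
    ``singles_fraction`` share of extra isolated particles reproduces the
    broad length distribution with singles seen in dilute aggregating
    systems.  Interior chain particles have exactly two bonded neighbors,
    giving mean coordination ≈ 2 for long chains.
    """
    rng = np.random.default_rng(seed)
    Lx, Ly = float(box[0]), float(box[1])
    if chain_length_distribution is None:
        def chain_length_distribution(r: np.random.Generator) -> int:
            return 1 + r.geometric(1.0 / 4.0)  # broad, mean 5, min 2

    min_sep = min_sep_factor * bond_distance
    placed: list[np.ndarray] = []

    def clashes(pt: np.ndarray, skip_last: int = 0) -> bool:
        for q in placed[: len(placed) - skip_last]:
            d = pt - q
            d -= np.array([Lx, Ly]) * np.round(d / np.array([Lx, Ly]))
            if (d**2).sum() < min_sep**2:
                return True
        return False

    for _ in range(n_chains):
        length = chain_length_distribution(rng)
        for _attempt in range(max_retries):
            start = rng.random(2) * np.array([Lx, Ly])
            if clashes(start):
                continue
            pts = [start]
            angle = rng.uniform(0, 2 * np.pi)
            ok = True
            for _k in range(length - 1):
                grown = False
                for _try in range(20):
                    cand = (pts[-1] + bond_distance
                            * np.array([np.cos(angle), np.sin(angle)]))
                    cand %= np.array([Lx, Ly])
                    prev = placed + pts[:-1]
                    clash = False
                    for q in prev:
                        d = cand - q
                        d -= np.array([Lx, Ly]) * np.round(d / np.array([Lx, Ly]))
                        if (d**2).sum() < min_sep**2:
                            clash = True
                            break
                    if not clash:
                        pts.append(cand)
                        angle += rng.uniform(-turn_angle, turn_angle)
                        grown = True
                        break
                    angle = rng.uniform(0, 2 * np.pi)
                if not grown:
                    ok = False
                    break
            if ok:
                placed.extend(pts)
                break
        else:
            raise RuntimeError(
                "chain placement failed after bounded retries; reduce "
                "n_chains or the bond distance"
            )
    n_singles = int(round(singles_fraction * len(placed)))
    for _ in range(n_singles):
        for _attempt in range(max_retries):
            pt = rng.random(2) * np.array([Lx, Ly])
            if not clashes(pt):
                placed.append(pt)
                break
        else:
            raise RuntimeError("single-particle placement failed; box too full")
    return Configuration2D(np.asarray(placed), (Lx, Ly))


def gen_brownian_tracks(n: int, D: float, n_frames: int,
                        frame_interval: float = 1.0 / 15.0,
                        drift: Sequence[float] = (0.0, 0.0),
                        seed: int | np.random.Generator = 0) -> TrackSet:
    """Independent 2D Gaussian random walks with optional uniform drift.

    Per-axis step variance is 2·D·frame_interval, so the ensemble MSD is
    4·D·Δt (+ |v|²Δt² with drift velocity v).
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * D * frame_interval)
    steps = rng.normal(0.0, step_sd, size=(n, n_frames - 1, 2))
    steps += np.asarray(drift, dtype=float) * frame_interval
    pos = np.concatenate(
        [np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    pos += rng.random((n, 1, 2)) * 10.0  # random starting points
    frames = np.tile(np.arange(n_frames), n)
    ids = np.repeat(np.arange(n), n_frames)
    df = pd.DataFrame(
        {"frame": frames, "id": ids,
         "x": pos[:, :, 0].ravel(), "y": pos[:, :, 1].ravel()}
    )
    return TrackSet(df, frame_interval)


def experimental_brush_params() -> BrushGeometry:
    """Geometry of the experimental dsDNA brush: f = 10⁵ chains of 10 kbp
    dsDNA (one charge per 0.17 nm, N = 2×10⁴) on an R_PS = 0.49 μm core."""
    return BrushGeometry(f=1e5, N=2e4, R_PS=490.0)


def miniature_brush_params() -> BrushGeometry:
    """Scaled-down brush (N = 40, R_PS = 10 nm) at the experimental
    grafting density: f scaled by (10 nm / 490 nm)²."""
    ref = experimental_brush_params()
    f_mini = ref.f * (10.0 / ref.R_PS) ** 2
    return BrushGeometry(f=f_mini, N=40.0, R_PS=10.0)
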