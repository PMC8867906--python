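"""Wigner–Seitz cell model of a spherical polyelectrolyte brush.

A colloidal core of radius ``R_PS`` carries ``f`` grafted polyelectrolyte
chains of ``N`` charged monomers each (for dsDNA, one elementary charge per
``b`` = 0.17 nm of contour).  The brush plus its ``N·f`` monovalent
counterions live in a spherical Wigner–Seitz cell of radius ``R_W`` that
encodes the suspension packing fraction.  Counterions split into three
populations:

* ``N1`` — Manning-condensed on the chains (one net charge per Bjerrum
  length survives condensation),
* ``N2`` — free inside the brush (radius ``R = R_PS + L``),
* ``N3`` — free in the outer shell ``R < r < R_W``,

with charge neutrality ``N1 + N2 + N3 = N·f``.  The equilibrium brush
thickness ``L`` and escaped-counterion count ``N3`` minimize a variational
free energy with six contributions (all in units of k_B T):

``F = U_H + F_el + F_Fl − T·S2 − T·S3 + F_p``

* ``U_H`` — Hartree (mean-field Coulomb) energy of the net charge profile,
* ``F_el`` — Gaussian stretching penalty of the chains,
* ``F_Fl`` — Flory excluded-volume repulsion between monomers,
* ``−T·S2, −T·S3`` — ideal-gas entropy of the two free populations
  (with a chain-excluded free-volume correction inside the brush),
* ``F_p`` — osmotic insertion cost exerted by the counterions of the
  surrounding brushes, ``N2·kT·(R/R_W)³``.

Lengths are in nanometres, energies in k_B T throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import constants as _const
from scipy import integrate, optimize

__all__ = [
    "BrushGeometry",
    "CellState",
    "FreeEnergyBreakdown",
    "EquilibriumResult",
    "OsmoticLimitWarning",
    "UnphysicalStateError",
    "bjerrum_length",
    "manning_condensed",
    "make_state",
    "charge_density",
    "hartree_energy",
    "hartree_from_profile",
    "elastic_energy",
    "flory_energy",
    "counterion_entropy",
    "ideal_gas_free_energy",
    "insertion_free_energy",
    "total_free_energy",
    "minimize_free_energy",
    "size_vs_packing",
]


class UnphysicalStateError(ValueError):
    """Raised when a trial state violates a physical bound (e.g. monomers
    overfilling the brush shell)."""


class OsmoticLimitWarning(UserWarning):
    """The insertion term assumes N2 >> N3; emitted when that fails."""


# --------------------------------------------------------------------------
# geometry and state containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BrushGeometry:
    """Physical parameters of one spherical polyelectrolyte brush.

    Parameters
    ----------
    f : float
        Number of grafted chains (functionality).
    N : float
        Charged monomers per chain; treated as continuous, ``N = L_C/b``.
    R_PS : float
        Core radius [nm].
    b : float
        Spacing between adjacent chain charges [nm]; 0.17 for dsDNA
        (two charges per 0.34 nm base-pair rise).
    R_m : float
        Monomer radius used for the Flory excluded volume [nm].
    d : float
        Counterion diameter (entropy length scale) [nm].
    T : float
        Temperature [K].
    eps_r : float
        Relative permittivity of the solvent.
    """

    f: float
    N: float
    R_PS: float
    b: float = 0.17
    R_m: float = 1.0
    d: float = 0.7
    T: float = 298.0
    eps_r: float = 78.5

    def __post_init__(self) -> None:
        for name in ("f", "N", "R_PS", "b", "R_m", "d", "T", "eps_r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BrushGeometry.{name} must be strictly positive")

    @property
    def contour_length(self) -> float:
        """Fully stretched brush thickness L_C = N·b [nm]."""
        return self.N * self.b

    @property
    def lambda_B(self) -> float:
        """Bjerrum length [nm]."""
        return bjerrum_length(self.T, self.eps_r)

    @property
    def xi(self) -> float:
        """Manning parameter ξ = λ_B / b."""
        return self.lambda_B / self.b

    @property
    def total_charge(self) -> float:
        """Bare charge count N·f (in units of e)."""
        return self.N * self.f

    @property
    def grafting_density(self) -> float:
        """Chains per core surface area, f / (4π R_PS²) [nm⁻²]."""
        return self.f / (4.0 * np.pi * self.R_PS**2)


@dataclass(frozen=True)
class CellState:
    """Counterion partition and brush thickness inside one Wigner–Seitz cell.

    Invariants: ``N1 + N2 + N3 = N·f``, ``0 ≤ L ≤ L_C``,
    ``R_PS + L ≤ R_W``, all populations non-negative.
    """

    R_W: float
    L: float
    N1: float
    N2: float
    N3: float

    def R(self, geom: BrushGeometry) -> float:
        """Outer brush radius R_PS + L [nm]."""
        return geom.R_PS + self.L


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """The six free-energy contributions at one (L, N3) point, in k_B T.

    ``TS2`` and ``TS3`` store the *signed free-energy contributions*
    −T·S2 and −T·S3, so ``total`` is the plain sum of the six fields.
    """

    U_H: float
    F_el: float
    F_Fl: float
    TS2: float
    TS3: float
    F_p: float

    @property
    def total(self) -> float:
        return self.U_H + self.F_el + self.F_Fl + self.TS2 + self.TS3 + self.F_p


@dataclass(frozen=True)
class EquilibriumResult:
    """Minimizer of the cell free energy over (L, N3)."""

    L_star: float
    N3_star: float
    breakdown: FreeEnergyBreakdown
    converged: bool
    release_fraction: float
    R_W: float
    state: CellState


# --------------------------------------------------------------------------
# elementary quantities
# --------------------------------------------------------------------------


def bjerrum_length(T: float, eps_r: float) -> float:
    """Bjerrum length λ_B = e²/(4π ε₀ ε_r k_B T) in nm.

    ≈ 0.71 nm for water (ε_r = 78.5) at 298 K.
    """
    if T <= 0 or eps_r <= 0:
        raise ValueError("T and eps_r must be strictly positive")
    lam_m = _const.e**2 / (
        4.0 * np.pi * _const.epsilon_0 * eps_r * _const.k * T
    )
    return lam_m * 1e9


def manning_condensed(geom: BrushGeometry) -> float:
    """Number of Manning-condensed counterions N1.

    For ξ = λ_B/b > 1 condensation leaves one net charge per Bjerrum
    length along each chain: N1 = N·f·(1 − 1/ξ).  Below the threshold
    (ξ ≤ 1) nothing condenses.
    """
    xi = geom.xi
    if xi <= 1.0:
        return 0.0
    return geom.total_charge * (1.0 - 1.0 / xi)


def make_state(geom: BrushGeometry, R_W: float, L: float, N3: float) -> CellState:
    """Build a charge-neutral CellState at given (L, N3).

    N1 comes from Manning condensation, N2 from neutrality.
    """
    if not 0.0 <= L <= geom.contour_length:
        raise ValueError(f"L = {L} outside [0, L_C = {geom.contour_length}]")
    if geom.R_PS + L > R_W:
        raise ValueError("brush does not fit in the cell: R_PS + L > R_W")
    if N3 < 0:
        raise ValueError("N3 must be non-negative")
    N1 = manning_condensed(geom)
    N2 = geom.total_charge - N1 - N3
    if N2 < 0:
        raise ValueError("N3 exceeds the uncondensed counterion budget")
    return CellState(R_W=R_W, L=L, N1=N1, N2=N2, N3=N3)


# --------------------------------------------------------------------------
# charge profile and Hartree energy
# --------------------------------------------------------------------------


def charge_density(r, state: CellState, geom: BrushGeometry):
    """Net charge density ρ(r) in units of e/nm³.

    The chains and both in-brush counterion populations share the stretched
    r⁻² profile, so the net density inside the brush is −N3 distributed as
    r⁻², compensated by a uniform +N3 in the outer shell; zero in the core.
    Integrates to zero over the cell by construction.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > state.R_W * (1 + 1e-12)):
        raise ValueError("r outside [0, R_W]")
    R = state.R(geom)
    delta = R - geom.R_PS
    rho = np.zeros_like(r_arr)
    if state.N3 > 0 and delta > 0:
        inside = (r_arr >= geom.R_PS) & (r_arr < R)
        with np.errstate(divide="ignore"):
            rho[inside] = -state.N3 / (4.0 * np.pi * delta * r_arr[inside] ** 2)
        shell_vol = 4.0 * np.pi / 3.0 * (state.R_W**3 - R**3)
        if shell_vol > 0:
            rho[r_arr >= R] = state.N3 / shell_vol
    return rho if np.ndim(r) else float(rho)


def hartree_energy(state: CellState, geom: BrushGeometry,
                   method: Literal["analytic", "quadrature"] = "analytic") -> float:
    """Mean-field electrostatic (Hartree) energy of the cell, in k_B T.

    Evaluates (1/2)∫∫ ρ(r)ρ(r′)/(4πε|r−r′|) for the spherically symmetric
    profile of :func:`charge_density` via the equivalent assembly-work
    integral λ_B ∫ q(r) ρ(r) 4π r dr, with q(r) the cumulative charge.
    Piecewise-analytic antiderivatives are used by default; adaptive
    quadrature is available as a cross-check.
    """
    N3 = state.N3
    if N3 == 0:
        return 0.0
    R = state.R(geom)
    delta = R - geom.R_PS
    if delta <= 0:
        raise ValueError("brush thickness must be positive when N3 > 0")
    W = state.R_W**3 - R**3
    if W <= 0:
        raise ValueError("no outer shell available for escaped counterions")
    lam = geom.lambda_B
    if method == "quadrature":
        return hartree_from_profile(
            lambda r: charge_density(r, state, geom), state.R_W, lam,
            points=[geom.R_PS, R],
        )
    # inside: q(r) = -N3 (r-R_PS)/Δ, ρ = -N3/(4πΔr²)
    u_in = (N3**2 / delta**2) * (delta - geom.R_PS * np.log(R / geom.R_PS))
    # outer shell: q(r) = N3 (r³ - R_W³)/W, ρ = 3N3/(4πW);
    # ∫(r⁴ - R_W³ r)dr factored to avoid cancellation as R → R_W
    a, B = R, state.R_W
    gap = B - a
    W_stable = gap * (B**2 + B * a + a**2)
    integral = -(gap**2) * (2 * a**3 + 4 * B * a**2 + 6 * B**2 * a + 3 * B**3) / 10.0
    u_out = 3.0 * N3**2 * integral / W_stable**2
    return lam * (u_in + u_out)


def hartree_from_profile(rho: Callable[[float], float], r_max: float,
                         lam_B: float, points: Sequence[float] = ()) -> float:
    """Hartree energy (k_B T) of an arbitrary spherical profile by quadrature.

    ``rho`` is in e/nm³; the assembly-work form λ_B ∫ q(r)ρ(r)4πr dr is used
    with q(r) obtained by adaptive radial quadrature.  Serves as the
    independent oracle for :func:`hartree_energy`.
    """
    pts = sorted(set(float(p) for p in points if 0 < p < r_max))

    def q(r: float) -> float:
        val, _ = integrate.quad(
            lambda s: rho(s) * 4.0 * np.pi * s**2, 0.0, r,
            points=[p for p in pts if p < r] or None, limit=200,
        )
        return val

    val, err = integrate.quad(
        lambda r: q(r) * rho(r) * 4.0 * np.pi * r, 0.0, r_max,
        points=pts or None, limit=200,
    )
    if not np.isfinite(val):
        raise RuntimeError(f"Hartree quadrature failed: value={val}, err={err}")
    return lam_B * val


# --------------------------------------------------------------------------
# elastic, Flory, entropic and osmotic terms
# --------------------------------------------------------------------------


def elastic_energy(state: CellState, geom: BrushGeometry) -> float:
    """Gaussian stretching penalty F_el = (3/2) f L² / (N b²), in k_B T."""
    if state.L > geom.contour_length * (1 + 1e-12):
        raise ValueError("L exceeds the contour length")
    return 1.5 * geom.f * state.L**2 / (geom.N * geom.b**2)


def flory_energy(state: CellState, geom: BrushGeometry) -> float:
    """Flory excluded-volume term F_Fl = (1/2) v_m (N f)² / V_brush, k_B T.

    The excluded volume is that of one monomer, v_m = (4/3)π R_m³, and the
    monomer density is taken uniform over the brush shell.
    """
    R = state.R(geom)
    v_brush = 4.0 * np.pi / 3.0 * (R**3 - geom.R_PS**3)
    if v_brush <= 0:
        raise ValueError("zero brush volume")
    v_m = 4.0 * np.pi / 3.0 * geom.R_m**3
    return 0.5 * v_m * geom.total_charge**2 / v_brush


def _free_volume_fraction(state: CellState, geom: BrushGeometry) -> float:
    """Fraction of the brush shell not occupied by chain monomers."""
    R = state.R(geom)
    v_brush = 4.0 * np.pi / 3.0 * (R**3 - geom.R_PS**3)
    v_mon = 4.0 * np.pi / 3.0 * geom.R_m**3 * geom.total_charge
    alpha = 1.0 - v_mon / v_brush
    if alpha <= 0:
        raise UnphysicalStateError(
            f"monomers overfill the brush shell (occupied fraction "
            f"{v_mon / v_brush:.3f} >= 1)"
        )
    return alpha


def ideal_gas_free_energy(n_func: Callable[[float], float], r_lo: float,
                          r_hi: float, d: float, alpha: float = 1.0) -> float:
    """−T·S of an inhomogeneous ideal gas by radial quadrature, in k_B T.

    ∫ n(r) [ln(n(r) d³/α) − 1] 4π r² dr over [r_lo, r_hi]; ``alpha`` is the
    accessible free-volume fraction.  Independent oracle for the closed
    forms used in :func:`counterion_entropy`.
    """

    def integrand(r: float) -> float:
        n = n_func(r)
        if n <= 0:
            return 0.0
        return n * (np.log(n * d**3 / alpha) - 1.0) * 4.0 * np.pi * r**2

    val, _ = integrate.quad(integrand, r_lo, r_hi, limit=200)
    return val


def counterion_entropy(state: CellState, geom: BrushGeometry,
                       region: Literal["inside", "outside"]) -> float:
    """Entropic free-energy contribution −T·S of one free population, k_B T.

    inside  : N2 ions on the r⁻² brush profile, with the chain-excluded
              free-volume correction (accessible fraction α < 1).
    outside : N3 ions uniform in the shell R < r < R_W.

    Zero when the population is empty.  Negative values mean the entropy
    lowers the free energy.
    """
    R = state.R(geom)
    if region == "inside":
        if state.N2 <= 0:
            return 0.0
        delta = R - geom.R_PS
        if delta <= 0:
            raise ValueError("brush thickness must be positive when N2 > 0")
        alpha = _free_volume_fraction(state, geom)
        C = state.N2 / (4.0 * np.pi * delta)  # n2(r) = C / r²
        return state.N2 * (np.log(C * geom.d**3 / alpha) - 1.0) - (
            2.0 * state.N2 / delta
        ) * (R * np.log(R) - geom.R_PS * np.log(geom.R_PS) - delta)
    elif region == "outside":
        if state.N3 <= 0:
            return 0.0
        shell_vol = 4.0 * np.pi / 3.0 * (state.R_W**3 - R**3)
        if shell_vol <= 0:
            raise ValueError("no outer shell volume for N3 > 0")
        n3 = state.N3 / shell_vol
        return state.N3 * (np.log(n3 * geom.d**3) - 1.0)
    raise ValueError(f"unknown region {region!r}")


def insertion_free_energy(state: CellState, geom: BrushGeometry) -> float:
    """Osmotic insertion cost F_p = N2 · (R/R_W)³, in k_B T.

    The counterions trapped in the surrounding brushes exert an osmotic
    pressure Π(R_W) ∝ N2/R_W³; inserting a brush of volume ∝ R³ costs
    Π·R³.  Valid in the osmotic limit N2 ≫ N3 (a warning is emitted
    otherwise).
    """
    R = state.R(geom)
    if R > state.R_W:
        raise ValueError("R > R_W")
    if state.N2 <= 0:
        return 0.0
    if state.N3 > 0 and state.N2 < 10.0 * state.N3:
        warnings.warn(
            "insertion term outside its validity regime (N2 >> N3 violated)",
            OsmoticLimitWarning,
            stacklevel=2,
        )
    return state.N2 * (R / state.R_W) ** 3


# --------------------------------------------------------------------------
# total free energy and minimization
# --------------------------------------------------------------------------


def total_free_energy(L: float, N3: float, geom: BrushGeometry,
                      R_W: float) -> FreeEnergyBreakdown:
    """All six free-energy terms at one (L, N3) point (k_B T units)."""
    state = make_state(geom, R_W, L, N3)
    return FreeEnergyBreakdown(
        U_H=hartree_energy(state, geom),
        F_el=elastic_energy(state, geom),
        F_Fl=flory_energy(state, geom),
        TS2=counterion_entropy(state, geom, "inside"),
        TS3=counterion_entropy(state, geom, "outside"),
        F_p=insertion_free_energy(state, geom),
    )


def _objective(L: float, N3: float, geom: BrushGeometry, R_W: float,
               L_bounds: tuple[float, float], N3_max: float) -> float:
    if not (L_bounds[0] <= L <= L_bounds[1]) or not (0.0 <= N3 <= N3_max):
        return np.inf
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OsmoticLimitWarning)
            return total_free_energy(L, N3, geom, R_W).total
    except (UnphysicalStateError, ValueError):
        return np.inf


def minimize_free_energy(geom: BrushGeometry, R_W: float, *, n_L: int = 40,
                         n_N3: int = 40, L_min_frac: float = 0.05,
                         rel_tol: float = 1e-6) -> EquilibriumResult:
    """Minimize F(L, N3) over the feasible box; returns the equilibrium.

    Strategy: a coarse scan on a linear grid in L × logarithmic grid in N3
    (N3 spans many decades), followed by Nelder–Mead refinement in
    (L, ln N3).  ``converged`` requires the refinement to agree with (or
    improve on) the grid optimum within ``rel_tol`` and to stay interior
    or on the feasible boundary.
    """
    if R_W <= geom.R_PS:
        raise ValueError("R_W must exceed the core radius")
    L_C = geom.contour_length
    L_lo = L_min_frac * L_C
    L_hi = min(L_C, (R_W - geom.R_PS) * (1.0 - 1e-9))
    if L_hi <= L_lo:
        L_lo = 0.5 * L_hi
    N1 = manning_condensed(geom)
    N3_cap = max((geom.total_charge - N1) * (1.0 - 1e-9), 0.0)

    L_grid = np.linspace(L_lo, L_hi, n_L)
    N3_grid = np.concatenate(
        [[0.0], np.geomspace(max(geom.total_charge * 1e-12, 1e-12),
                             max(N3_cap, 1e-12), n_N3 - 1)]
    ) if N3_cap > 0 else np.array([0.0])

    F = np.full((len(L_grid), len(N3_grid)), np.inf)
    for i, L in enumerate(L_grid):
        for j, n3 in enumerate(N3_grid):
            F[i, j] = _objective(L, n3, geom, R_W, (L_lo, L_hi), N3_cap)
    if not np.isfinite(F).any():
        raise RuntimeError("no feasible point found on the (L, N3) scan grid")
    i0, j0 = np.unravel_index(np.nanargmin(np.where(np.isfinite(F), F, np.nan)),
                              F.shape)
    L0, N30, F0 = L_grid[i0], N3_grid[j0], F[i0, j0]

    # local refinement: Nelder-Mead in (L, u = ln N3) with bound penalties
    n3_floor = max(geom.total_charge * 1e-15, 1e-15)
    u0 = np.log(max(N30, n3_floor))

    def fun(x):
        return _objective(x[0], np.exp(x[1]), geom, R_W, (L_lo, L_hi), N3_cap)

    res = optimize.minimize(
        fun, np.array([L0, u0]), method="Nelder-Mead",
        options={"xatol": 1e-8 * max(L_C, 1.0), "fatol": rel_tol * max(abs(F0), 1.0),
                 "maxiter": 4000},
    )
    L_star, N3_star, F_star = L0, N30, F0
    if res.fun <= F0:
        L_star, N3_star, F_star = res.x[0], float(np.exp(res.x[1])), res.fun
    # a polished N3 below the grid floor is numerically zero
    if N3_star <= 2.0 * n3_floor:
        F_zero = _objective(L_star, 0.0, geom, R_W, (L_lo, L_hi), N3_cap)
        if F_zero <= F_star:
            N3_star, F_star = 0.0, F_zero
    converged = bool(
        np.isfinite(F_star)
        and (F_star <= F0 + rel_tol * max(abs(F0), 1.0))
    )
    state = make_state(geom, R_W, L_star, N3_star)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OsmoticLimitWarning)
        breakdown = total_free_energy(L_star, N3_star, geom, R_W)
    return EquilibriumResult(
        L_star=L_star,
        N3_star=N3_star,
        breakdown=breakdown,
        converged=converged,
        release_fraction=N3_star / geom.total_charge,
        R_W=R_W,
        state=state,
    )


def size_vs_packing(geom: BrushGeometry, eta_grid: Sequence[float],
                    sigma0: float | None = None, **minimize_kwargs) -> pd.DataFrame:
    """Equilibrium brush diameter across a packing-fraction sweep.

    For each η the Wigner–Seitz radius is R_W = R_0 η^(−1/3) with
    R_0 = R_PS + L_C (the 3D cell convention η = R_0³/R_W³), the free
    energy is minimized, and the reduced diameter 2(R_PS + L*)/σ0 is
    recorded.  Returns a DataFrame with one row per η: eta, R_W, L_star,
    N1, N2, N3, release_fraction, sigma_ratio and the six energy terms.
    """
    eta_arr = np.asarray(list(eta_grid), dtype=float)
    if np.any(eta_arr <= 0) or np.any(eta_arr > 1.3):
        raise ValueError("eta values must lie in (0, 1.3]")
    R_0 = geom.R_PS + geom.contour_length
    if sigma0 is None:
        sigma0 = 2.0 * R_0
    rows = []
    for eta in eta_arr:
        R_W = R_0 * eta ** (-1.0 / 3.0)
        eq = minimize_free_energy(geom, R_W, **minimize_kwargs)
        b = eq.breakdown
        rows.append(
            {
                "eta": eta,
                "R_W": R_W,
                "L_star": eq.L_star,
                "N1": eq.state.N1,
                "N2": eq.state.N2,
                "N3": eq.state.N3,
                "release_fraction": eq.release_fraction,
                "sigma_ratio": 2.0 * (geom.R_PS + eq.L_star) / sigma0,
                "U_H": b.U_H,
                "F_el": b.F_el,
                "F_Fl": b.F_Fl,
                "TS2": b.TS2,
                "TS3": b.TS3,
                "F_p": b.F_p,
                "F_total": b.total,
                "converged": eq.converged,
            }
        )
    return pd.DataFrame(rows)
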