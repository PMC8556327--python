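"""Sedimentation-velocity analysis: Lamm equation, c(s) inversion, Svedberg.

A sedimentation-velocity experiment observes absorbance profiles a(r, t) in
a spinning sector cell.  The concentration of each ideal species obeys the
Lamm equation

    dc/dt = (1/r) d/dr [ r ( D dc/dr - s w^2 r c ) ],

with zero total flux at the meniscus r_m and cell bottom r_b.  The forward
solver here is a conservative Crank-Nicolson finite-volume scheme on a
uniform radial grid; because fluxes telescope, total mass in the closed cell
is conserved to round-off.

The continuous c(s) distribution inverts scans as a non-negative, Tikhonov-
regularized superposition of single-species Lamm solutions, with the
diffusion coefficient of each s tied to a single frictional ratio f/f0
through the standard hydrodynamic scaling.  Sedimentation coefficients are
standardized to water at 20 C (s20,w) and converted to molar masses with the
Svedberg equation.

Public APIs take s in Svedberg units (1 S = 1e-13 s), radii in cm, times in
seconds, density in g/mL, viscosity in poise and vbar in mL/g (CGS).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.optimize import nnls

__all__ = [
    "HydroParams",
    "SedimentationDataset",
    "CSDistribution",
    "SpeciesEstimate",
    "WATER_20C",
    "DEFAULT_BUFFER",
    "s20w_correction",
    "diffusion_from_s",
    "svedberg_mass",
    "sphere_s_from_mass",
    "lamm_simulate",
    "cell_mass",
    "fit_cs",
    "peaks_to_species",
    "assign_oligomer",
    "cpc_concentration",
    "read_scan_csv",
    "write_scan_csv",
]

# CGS constants
R_GAS = 8.314462618e7        # erg / (mol K)
K_B = 1.380649e-16           # erg / K
N_A = 6.02214076e23          # 1 / mol
SVEDBERG = 1e-13             # s
RHO_W20 = 0.998234           # g/mL, water at 20 C
ETA_W20 = 0.010020           # poise, water at 20 C
PECLET_MAX = 2.0             # cell Peclet limit for the central CN scheme


@dataclass(frozen=True)
class HydroParams:
    """Buffer and rotor parameters of a sedimentation-velocity run."""

    rho: float                 # solution density, g/mL
    eta: float                 # solution viscosity, poise
    vbar: float                # partial specific volume, mL/g
    temperature: float = 293.15  # K
    rotor_speed: float = 60000.0  # rpm

    def __post_init__(self):
        for name in ("rho", "eta", "vbar", "temperature", "rotor_speed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(1.0 - self.vbar * self.rho) < 1e-12:
            raise ValueError("buoyancy factor (1 - vbar*rho) vanishes")

    @property
    def omega(self) -> float:
        """Angular velocity, rad/s."""
        return self.rotor_speed * 2.0 * math.pi / 60.0

    @property
    def buoyancy(self) -> float:
        return 1.0 - self.vbar * self.rho


WATER_20C = HydroParams(rho=RHO_W20, eta=ETA_W20, vbar=0.73149)

#: 10 mM potassium phosphate pH 7.0 at 20 C, with the vbar of the
#: C-phycocyanin (alpha-beta) unit computed from its sequence.
DEFAULT_BUFFER = HydroParams(rho=1.00980, eta=0.01029, vbar=0.73149)


@dataclass
class SedimentationDataset:
    """Radius x time absorbance scans from one cell."""

    radii: np.ndarray            # cm, strictly increasing
    times: np.ndarray            # s
    scans: np.ndarray            # (n_times, n_radii)
    wavelength: float = 277.0    # nm
    meniscus: float | None = None
    bottom: float | None = None

    def __post_init__(self):
        self.radii = np.asarray(self.radii, float)
        self.times = np.asarray(self.times, float)
        self.scans = np.asarray(self.scans, float)
        if self.radii.ndim != 1 or np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.scans.shape != (self.times.size, self.radii.size):
            raise ValueError("scans must have shape (n_times, n_radii)")
        if not np.all(np.isfinite(self.scans)):
            raise ValueError("scans contain non-finite values")
        if self.meniscus is None:
            self.meniscus = float(self.radii[0])
        if self.bottom is None:
            self.bottom = float(self.radii[-1])
        if not self.meniscus < self.bottom:
            raise ValueError("meniscus must lie inside the cell (r_m < r_b)")


@dataclass
class CSDistribution:
    """A fitted continuous c(s) distribution."""

    s_grid: np.ndarray           # Svedberg units, strictly increasing
    c: np.ndarray                # concentration density per S, >= 0
    f_ratio: float
    lambda_reg: float
    fit_rmsd: float

    def __post_init__(self):
        self.s_grid = np.asarray(self.s_grid, float)
        self.c = np.asarray(self.c, float)
        if np.any(np.diff(self.s_grid) <= 0):
            raise ValueError("s_grid must be strictly increasing")
        if np.any(self.c < -1e-12):
            raise ValueError("c(s) must be non-negative")


@dataclass
class SpeciesEstimate:
    s_obs: float                 # S
    s_20w: float                 # S
    D: float                     # cm^2/s
    M: float                     # Da
    loading: float               # absorbance units
    label: str = ""


# ---------------------------------------------------------------------------
# Hydrodynamic relations
# ---------------------------------------------------------------------------

def s20w_correction(s_obs: float, buffer: HydroParams,
                    vbar: float | None = None) -> float:
    """Standardize an observed s (Svedberg) to water at 20 C.

    s20,w = s_obs * (eta_buffer/eta_w20) * (1 - vbar*rho_w20)/(1 - vbar*rho_buffer)
    """
    vbar = buffer.vbar if vbar is None else vbar
    b_buf = 1.0 - vbar * buffer.rho
    b_w = 1.0 - vbar * RHO_W20
    if b_buf <= 0 or b_w <= 0:
        raise ValueError("buoyancy factor (1 - vbar*rho) must be positive")
    return s_obs * (buffer.eta / ETA_W20) * (b_w / b_buf)


def diffusion_from_s(s: float, f_ratio: float, buffer: HydroParams,
                     vbar: float | None = None) -> float:
    """Diffusion coefficient (cm^2/s) implied by s (Svedberg) and f/f0.

    D(s) = (sqrt(2)/(18 pi)) kT s^(-1/2) (eta f/f0)^(-3/2)
           ((1 - vbar rho)/vbar)^(1/2)
    """
    vbar = buffer.vbar if vbar is None else vbar
    if f_ratio < 1.0:
        raise ValueError("frictional ratio f/f0 < 1 is unphysical")
    s_sec = s * SVEDBERG
    kT = K_B * buffer.temperature
    return (math.sqrt(2.0) / (18.0 * math.pi) * kT / math.sqrt(s_sec)
            * (buffer.eta * f_ratio) ** -1.5
            * math.sqrt(buffer.buoyancy / vbar))


def svedberg_mass(s_obs: float, f_ratio: float, buffer: HydroParams,
                  vbar: float | None = None) -> SpeciesEstimate:
    """Molar mass and diffusion coefficient from s and a frictional ratio.

    M is solved from
        M^(2/3) = N_A s (f/f0) 6 pi eta (3 vbar/(4 pi N_A))^(1/3) / (1 - vbar rho)
    and D follows from the Svedberg relation D = s R T / (M (1 - vbar rho)).
    """
    vbar = buffer.vbar if vbar is None else vbar
    if f_ratio < 1.0:
        raise ValueError("frictional ratio f/f0 < 1 is unphysical")
    if buffer.buoyancy <= 0:
        raise ValueError("buoyancy factor must be positive")
    s_sec = s_obs * SVEDBERG
    m23 = (N_A * s_sec * f_ratio * 6.0 * math.pi * buffer.eta
           * (3.0 * vbar / (4.0 * math.pi * N_A)) ** (1.0 / 3.0)
           / buffer.buoyancy)
    M = m23 ** 1.5
    D = s_sec * R_GAS * buffer.temperature / (M * buffer.buoyancy)
    return SpeciesEstimate(s_obs=s_obs, s_20w=s20w_correction(s_obs, buffer, vbar),
                           D=D, M=M, loading=float("nan"))


def sphere_s_from_mass(M: float, buffer: HydroParams,
                       vbar: float | None = None, f_ratio: float = 1.0) -> float:
    """Sedimentation coefficient (Svedberg) of a compact particle of mass M (Da)."""
    vbar = buffer.vbar if vbar is None else vbar
    r0 = (3.0 * M * vbar / (4.0 * math.pi * N_A)) ** (1.0 / 3.0)
    f = f_ratio * 6.0 * math.pi * buffer.eta * r0
    s_sec = M * buffer.buoyancy / (N_A * f)
    return s_sec / SVEDBERG


# ---------------------------------------------------------------------------
# Lamm-equation forward solver
# ---------------------------------------------------------------------------

def _lamm_profiles(s_svedberg: float, D: float, omega: float,
                   r_m: float, r_b: float, times: np.ndarray,
                   n_cells: int, n_steps: int, loading: float,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Concentration profiles of one species at the requested times.

    Conservative finite volumes on a uniform grid with Crank-Nicolson time
    stepping; zero total flux at both ends.  Returns (cell centers, profiles).
    """
    s_sec = s_svedberg * SVEDBERG
    dr = (r_b - r_m) / n_cells
    centers = r_m + (np.arange(n_cells) + 0.5) * dr
    faces = r_m + np.arange(1, n_cells) * dr          # interior faces
    v_f = s_sec * omega ** 2 * faces                  # advection at faces

    if D > 0:
        pe = float(np.max(np.abs(v_f))) * dr / D if v_f.size else 0.0
        if pe > PECLET_MAX:
            need = int(math.ceil((r_b - r_m) * np.max(np.abs(v_f)) / (PECLET_MAX * D)))
            raise ValueError(
                f"cell Peclet number {pe:.2f} exceeds {PECLET_MAX}; "
                f"use a finer radial grid (>= {need} cells)")
    elif np.any(v_f != 0.0):
        raise ValueError("advection with zero diffusion needs D > 0")

    # Flux at interior face k (between cells k and k+1):
    #   F_k = r_f [ D (c_{k+1} - c_k)/dr - v_f (c_k + c_{k+1})/2 ]
    # d(c_i r_i dr)/dt = F_i - F_{i-1}; boundary fluxes are zero.
    lower = faces * (D / dr + v_f / 2.0)              # coefficient of c_k in F_k
    upper = faces * (D / dr - v_f / 2.0)              # coefficient of c_{k+1}
    # Tridiagonal A (mass-weighted): A @ c = dm/dt
    diag = np.zeros(n_cells)
    off_lo = np.zeros(n_cells - 1)
    off_up = np.zeros(n_cells - 1)
    # contribution of F_k to cell k:   + (-lower[k] c_k + upper[k] c_{k+1})
    diag[:-1] += -lower
    off_up[:] = upper
    # contribution of -F_{k} to cell k+1: -(-lower c_k + upper c_{k+1})
    diag[1:] += -upper
    off_lo[:] = lower

    w = centers * dr                                   # mass weights
    c = np.full(n_cells, float(loading))
    out = np.empty((times.size, n_cells))
    t_now = 0.0
    t_max = float(times.max()) if times.size else 0.0
    dt_target = t_max / max(n_steps, 1) if t_max > 0 else 1.0

    ab_cache: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}

    def matrices(dt: float):
        key = round(dt, 12)
        if key not in ab_cache:
            # LHS banded (M - dt/2 A), RHS tridiagonal (M + dt/2 A)
            ab = np.zeros((3, n_cells))
            ab[0, 1:] = -0.5 * dt * off_up
            ab[1, :] = w - 0.5 * dt * diag
            ab[2, :-1] = -0.5 * dt * off_lo
            ab_cache[key] = (ab, w + 0.5 * dt * diag, 0.5 * dt * off_lo,
                             0.5 * dt * off_up)
        return ab_cache[key]

    for k, t_out in enumerate(np.asarray(times, float)):
        span = t_out - t_now
        if span < -1e-9:
            raise ValueError("times must be non-decreasing")
        if span > 1e-12:
            sub = max(1, int(math.ceil(span / dt_target)))
            dt = span / sub
            ab, rdiag, rlo, rup = matrices(dt)
            for _ in range(sub):
                rhs = rdiag * c
                rhs[1:] += rlo * c[:-1]
                rhs[:-1] += rup * c[1:]
                c = solve_banded((1, 1), ab, rhs)
            t_now = t_out
        out[k] = c
    return centers, out


def lamm_simulate(species: Sequence[tuple[float, float, float]],
                  params: HydroParams,
                  geometry: tuple[float, float] = (6.0, 7.2),
                  times: Sequence[float] = (),
                  n_cells: int = 400,
                  n_steps: int = 600,
                  baseline: float = 0.0,
                  radii_out: np.ndarray | None = None) -> SedimentationDataset:
    """Forward-simulate scans for a mixture of ideal species.

    ``species`` is a list of (s [Svedberg], D [cm^2/s], loading [absorbance]);
    scans are the sum over species plus an optional constant baseline.
    Raises when the grid is too coarse for the cell Peclet limit of the
    central scheme.
    """
    r_m, r_b = geometry
    if not r_m < r_b:
        raise ValueError("meniscus must be left of the cell bottom")
    times = np.asarray(list(times), float)
    if times.size == 0:
        raise ValueError("at least one scan time is required")
    centers = None
    total = None
    for s, D, loading in species:
        if s <= 0 or D <= 0:
            raise ValueError("species need s > 0 and D > 0")
        if loading < 0:
            raise ValueError("loadings must be non-negative")
        centers, prof = _lamm_profiles(s, D, params.omega, r_m, r_b, times,
                                       n_cells, n_steps, loading)
        total = prof if total is None else total + prof
    if total is None:  # zero species: flat (noise-free) baseline scans
        dr = (r_b - r_m) / n_cells
        centers = r_m + (np.arange(n_cells) + 0.5) * dr
        total = np.zeros((times.size, n_cells))
    total = total + baseline
    if radii_out is not None:
        radii_out = np.asarray(radii_out, float)
        total = np.vstack([np.interp(radii_out, centers, row) for row in total])
        centers = radii_out
    return SedimentationDataset(radii=centers, times=times, scans=total,
                                meniscus=r_m, bottom=r_b)


def cell_mass(dataset: SedimentationDataset, scan_index: int) -> float:
    """Radially weighted total signal integral(c r dr) of one scan.

    Midpoint quadrature on the (uniform) radial grid: this is the quantity
    the finite-volume solver conserves; trapezoid weighting would undercount
    the boundary cells where the sedimented solute accumulates.
    """
    r = dataset.radii
    dr = float(np.mean(np.diff(r)))
    return float(np.sum(dataset.scans[scan_index] * r) * dr)


# ---------------------------------------------------------------------------
# c(s) inversion
# ---------------------------------------------------------------------------

def _kernel_matrix(data: SedimentationDataset, s_grid: np.ndarray,
                   f_ratio: float, buffer: HydroParams, vbar: float | None,
                   n_steps: int) -> np.ndarray:
    """Columns chi(s_k, D(s_k), r, t) evaluated on the data's (t, r) grid."""
    r_m, r_b = data.meniscus, data.bottom
    v_max = s_grid[-1] * SVEDBERG * buffer.omega ** 2 * r_b
    d_min = diffusion_from_s(s_grid[-1], f_ratio, buffer, vbar)
    n_cells = 200
    if v_max > 0:
        n_cells = max(n_cells, int(math.ceil(
            1.05 * (r_b - r_m) * v_max / (PECLET_MAX * d_min))))
    A = np.empty((data.times.size * data.radii.size, s_grid.size))
    for k, s in enumerate(s_grid):
        D = diffusion_from_s(s, f_ratio, buffer, vbar)
        centers, prof = _lamm_profiles(s, D, buffer.omega, r_m, r_b,
                                       data.times, n_cells, n_steps, 1.0)
        interp = np.vstack([np.interp(data.radii, centers, row) for row in prof])
        A[:, k] = interp.ravel()
    return A


def _solve_cs(A: np.ndarray, b: np.ndarray, s_grid: np.ndarray,
              lambda_reg: float) -> tuple[np.ndarray, float]:
    n_s = s_grid.size
    ds = float(np.mean(np.diff(s_grid)))
    Aq = A * ds                                   # quadrature: a = sum c_k chi ds
    L = np.zeros((n_s - 2, n_s))
    idx = np.arange(n_s - 2)
    L[idx, idx] = 1.0
    L[idx, idx + 1] = -2.0
    L[idx, idx + 2] = 1.0
    scale = lambda_reg * np.linalg.norm(Aq, "fro") / max(np.linalg.norm(L, "fro"), 1e-12)
    M = np.vstack([Aq, scale * L])
    rhs = np.concatenate([b, np.zeros(n_s - 2)])
    try:
        coef, _ = nnls(M, rhs, maxiter=50 * n_s)
    except RuntimeError as exc:
        raise RuntimeError(f"NNLS failed to converge within {50 * n_s} "
                           f"iterations: {exc}") from exc
    resid = Aq @ coef - b
    rmsd = float(np.sqrt(np.mean(resid ** 2)))
    return coef, rmsd


def fit_cs(data: SedimentationDataset,
           s_grid: np.ndarray | None = None,
           f_ratio: float | Literal["fit"] = 1.2,
           lambda_reg: float = 0.02,
           buffer: HydroParams = DEFAULT_BUFFER,
           vbar: float | None = None,
           n_steps: int = 600,
           exclude_meniscus: float = 0.01,
           exclude_bottom: float = 0.05) -> CSDistribution:
    """Fit a continuous c(s) distribution to sedimentation scans.

    Each s on the grid contributes a Lamm kernel with diffusion tied to one
    frictional ratio; c(s) >= 0 is found by NNLS with second-difference
    Tikhonov regularization (weight ``lambda_reg``, relative to the kernel
    matrix norm).  ``f_ratio="fit"`` runs a golden-section scan of f/f0 over
    [1.0, 2.5] minimizing the fit rmsd.

    Radii within ``exclude_meniscus`` / ``exclude_bottom`` (cm) of the cell
    ends are left out of the fit: the meniscus region and the steep
    back-diffusion layer at the bottom are exquisitely sensitive to the
    assumed cell geometry and would otherwise dominate the residual.
    """
    if not np.any(data.scans != 0.0):
        raise ValueError("all-zero scans: nothing to fit")
    if data.times.size < 2:
        raise ValueError("c(s) fitting needs at least two scan times")
    s_grid = np.linspace(1.0, 15.0, 100) if s_grid is None else np.asarray(s_grid, float)
    keep = ((data.radii >= data.meniscus + exclude_meniscus)
            & (data.radii <= data.bottom - exclude_bottom))
    if not keep.any():
        raise ValueError("fit range is empty after boundary exclusion")
    mask = np.tile(keep, data.times.size)
    b = data.scans.ravel()[mask]

    def solve_for(f: float) -> tuple[np.ndarray, float]:
        A = _kernel_matrix(data, s_grid, f, buffer, vbar, n_steps)[mask, :]
        return _solve_cs(A, b, s_grid, lambda_reg)

    if f_ratio == "fit":
        f_best, (coef, rmsd) = _golden_section(
            lambda f: solve_for(f), 1.0, 2.5, tol=5e-3)
    else:
        f_best = float(f_ratio)
        if f_best < 1.0:
            raise ValueError("frictional ratio f/f0 < 1 is unphysical")
        coef, rmsd = solve_for(f_best)
    return CSDistribution(s_grid=s_grid, c=coef, f_ratio=f_best,
                          lambda_reg=lambda_reg, fit_rmsd=rmsd)


def _golden_section(objective, lo: float, hi: float, tol: float):
    """Golden-section minimization; objective returns (state, value)."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    cache = {}

    def f(x):
        if x not in cache:
            cache[x] = objective(x)
        return cache[x]

    while (b - a) > tol:
        if f(c)[1] < f(d)[1]:
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    x_best = min(cache, key=lambda x: cache[x][1])
    return x_best, cache[x_best]


def peaks_to_species(dist: CSDistribution,
                     buffer: HydroParams = DEFAULT_BUFFER,
                     vbar: float | None = None,
                     rel_threshold: float = 0.05) -> list[SpeciesEstimate]:
    """Reduce a c(s) distribution to discrete species estimates.

    Local maxima above ``rel_threshold`` x max(c) seed peaks; each peak's s is
    the weighted centroid over its contiguous above-threshold support, its
    loading the integral of c over that support, and s20w/D/M follow from the
    distribution's frictional ratio.
    """
    c, s = dist.c, dist.s_grid
    if np.all(c <= 0):
        warnings.warn("flat/empty c(s) distribution: no species")
        return []
    thr = rel_threshold * float(c.max())
    above = c > thr
    species = []
    i = 0
    while i < c.size:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < c.size and above[j + 1]:
            j += 1
        seg = slice(i, j + 1)
        weight = c[seg]
        s_peak = float(np.sum(weight * s[seg]) / np.sum(weight))
        loading = float(np.trapezoid(weight, s[seg])) if j > i else \
            float(weight[0] * np.mean(np.diff(s)))
        est = svedberg_mass(s_peak, dist.f_ratio, buffer, vbar)
        est.loading = loading
        species.append(est)
        i = j + 1
    if not species:
        warnings.warn("no peaks above threshold")
    return species


def assign_oligomer(estimate: SpeciesEstimate, monomer_mass: float,
                    rel_tol: float = 0.15, max_n: int = 12) -> str | None:
    """Label a species ``(ab)_k`` when M is within rel_tol of k x monomer mass."""
    for k in range(1, max_n + 1):
        if abs(estimate.M - k * monomer_mass) <= rel_tol * k * monomer_mass:
            estimate.label = f"(ab)_{k}"
            return estimate.label
    return None


def cpc_concentration(a615: float, a652: float) -> float:
    """C-phycocyanin concentration (mg/mL) from 615/652 nm absorbances.

    concentration = (A615 - 0.474 A652) / 5.34; a negative result (possible
    with blank-subtraction artifacts) is returned with a warning.
    """
    if a615 < 0 or a652 < 0:
        raise ValueError("absorbances must be non-negative")
    conc = (a615 - 0.474 * a652) / 5.34
    if conc < 0:
        warnings.warn("negative concentration: check blank subtraction")
    return conc


# ---------------------------------------------------------------------------
# Scan file I/O
# ---------------------------------------------------------------------------

def write_scan_csv(dataset: SedimentationDataset, path: str | Path) -> Path:
    """One radius column plus one column per scan; header row = times (s)."""
    path = Path(path)
    df = pd.DataFrame(dataset.scans.T,
                      columns=[f"{t:.6g}" for t in dataset.times])
    df.insert(0, "radius_cm", dataset.radii)
    df.to_csv(path, index=False)
    return path


def read_scan_csv(path: str | Path, wavelength: float = 277.0,
                  meniscus: float | None = None,
                  bottom: float | None = None) -> SedimentationDataset:
    """Read a radius-by-time scan table.

    When meniscus/bottom are not given they are taken half a radial step
    outside the first/last radius (cell-center convention of the simulator).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("scan CSV needs a radius column and at least one scan")
    radii = df.iloc[:, 0].to_numpy(float)
    times = np.array([float(c) for c in df.columns[1:]])
    scans = df.iloc[:, 1:].to_numpy(float).T
    if radii.size > 1:
        half = float(np.mean(np.diff(radii))) / 2.0
        if meniscus is None:
            meniscus = float(radii[0]) - half
        if bottom is None:
            bottom = float(radii[-1]) + half
    return SedimentationDataset(radii=radii, times=times, scans=scans,
                                wavelength=wavelength,
                                meniscus=meniscus, bottom=bottom)
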