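"""Single-bubble Rayleigh-Plesset dynamics with an effective surface tension.

The model behind the pressure sensitivity of the subharmonic signal: a
phospholipid-coated microbubble (SonoVue, modal radius 2 um) whose shell is
summarised by a constant *effective* surface tension sigma between 0 N/m
(buckled shell) and 0.07 N/m (clean air/water interface).  Raising the
ambient (hydrostatic) pressure compresses the bubble isothermally according
to gas conservation,

    R0^3 (p0 + 2 sigma / R0) = C_ref ,

and the compressed bubble is driven by a pure sine at fixed peak-to-peak
pressure through the classical Rayleigh-Plesset equation with adiabatic gas
(gamma = 1.4) and viscous damping.  The steady-state oscillation amplitude
Delta R0, mapped through

    A = 27 + 20 log10( (Delta R0 / Delta R_ref) * (p_ref / p0) )  [dB],

predicts the subharmonic amplitude as a function of hydrostatic pressure and
shell state; ``amplitude_surface`` tabulates it over a (pressure, sigma)
grid.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .calibration import ATM_PA, mmhg_to_pa

__all__ = [
    "BubbleParams",
    "Excitation",
    "EquilibriumState",
    "RadiusTrace",
    "AmplitudeSurface",
    "BubbleCollapseError",
    "RayleighPlessetModel",
    "gas_constant",
    "equilibrium_radius",
    "simulate_rp",
    "oscillation_amplitude",
    "predicted_amplitude",
    "amplitude_surface",
    "linear_resonance_frequency",
]

log = logging.getLogger(__name__)

#: Effective surface tension of a clean air/water interface, N/m (elastic
#: shell state); the buckled state is 0.
SIGMA_AIR_WATER = 0.07


class BubbleCollapseError(RuntimeError):
    """Raised when the integration enters an inertial-collapse regime."""

    def __init__(self, message: str, t_failure: float):
        super().__init__(message)
        self.t_failure = t_failure


@dataclass(frozen=True)
class BubbleParams:
    """Bubble plus host-liquid description at the reference state.

    Attributes
    ----------
    r_ref : float
        Equilibrium radius at the reference pressure, m (2 um for SonoVue).
    sigma : float
        Effective surface tension, N/m; 0 (buckled) to 0.07 (air/water).
    p_ref : float
        Reference ambient pressure, Pa absolute (1 atm).
    gamma : float
        Polytropic exponent of the gas; 1.4 = adiabatic air.
    rho : float
        Liquid density, kg/m^3.
    mu : float
        Liquid shear viscosity, Pa s (0 allowed: undamped).
    """

    r_ref: float = 2.0e-6
    sigma: float = SIGMA_AIR_WATER
    p_ref: float = ATM_PA
    gamma: float = 1.4
    rho: float = 998.0
    mu: float = 1.0e-3

    def __post_init__(self) -> None:
        if not self.r_ref > 0:
            raise ValueError(f"r_ref must be > 0, got {self.r_ref}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.sigma > SIGMA_AIR_WATER:
            warnings.warn(
                f"sigma={self.sigma} N/m exceeds the air/water value "
                f"{SIGMA_AIR_WATER}; outside the shell-state interpretation",
                stacklevel=3,
            )
        if not self.p_ref > 0:
            raise ValueError(f"p_ref must be > 0, got {self.p_ref}")
        if self.gamma < 1:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")


@dataclass(frozen=True)
class Excitation:
    """Pure-sine acoustic drive at fixed peak-to-peak pressure."""

    f: float = 4.0e6
    p_pp: float = 150.0e3
    n_cycles_total: int = 200
    waveform: str = "pure_sine"

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ValueError(f"drive frequency must be > 0, got {self.f}")
        if self.p_pp < 0:
            raise ValueError(f"p_pp must be >= 0, got {self.p_pp}")
        if self.n_cycles_total < 20:
            raise ValueError(
                f"n_cycles_total must be >= 20, got {self.n_cycles_total}"
            )
        if self.waveform != "pure_sine":
            raise ValueError(f"unsupported waveform {self.waveform!r}")


@dataclass(frozen=True)
class EquilibriumState:
    """Compressed equilibrium at ambient pressure ``p0`` (absolute)."""

    p0: float
    r0: float
    c_ref: float

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError(f"r0 must be > 0, got {self.r0}")
        if not self.p0 > 0 or not self.c_ref > 0:
            raise ValueError("p0 and c_ref must be > 0")


@dataclass
class RadiusTrace:
    """Uniformly sampled radius time series from the ODE integration."""

    t: np.ndarray
    r: np.ndarray
    steady_start: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.t.shape != self.r.shape:
            raise ValueError("t and r must have the same length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.r <= 0):
            raise ValueError("radius trace must be positive everywhere")
        if not 0 <= self.steady_start < len(self.t):
            raise ValueError("steady_start outside the trace")

    @property
    def steady_r(self) -> np.ndarray:
        return self.r[self.steady_start:]

    def plot(self, ax=None):
        """Plot R(t); steady-state window shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t * 1e6, self.r * 1e6, lw=0.7)
        ax.axvspan(self.t[self.steady_start] * 1e6, self.t[-1] * 1e6,
                   alpha=0.15, color="C1", label="steady state")
        ax.set_xlabel("time (us)")
        ax.set_ylabel("radius (um)")
        ax.legend()
        return ax


@dataclass
class AmplitudeSurface:
    """Predicted subharmonic amplitude over (hydrostatic pressure, sigma)."""

    p0_grid_mmhg: np.ndarray
    sigma_grid: np.ndarray
    a_db: np.ndarray  # shape (len(sigma_grid), len(p0_grid))
    dr_ref: float

    def __post_init__(self) -> None:
        self.p0_grid_mmhg = np.asarray(self.p0_grid_mmhg, dtype=float)
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)
        self.a_db = np.asarray(self.a_db, dtype=float)
        if self.a_db.shape != (len(self.sigma_grid), len(self.p0_grid_mmhg)):
            raise ValueError("a_db shape must be (n_sigma, n_pressure)")

    def to_frame(self):
        """Long-format DataFrame: p_mmHg, sigma_Npm, A_dB."""
        import pandas as pd

        pp, ss = np.meshgrid(self.p0_grid_mmhg, self.sigma_grid)
        return pd.DataFrame(
            {"p_mmHg": pp.ravel(), "sigma_Npm": ss.ravel(),
             "A_dB": self.a_db.ravel()}
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = ax.pcolormesh(self.p0_grid_mmhg, self.sigma_grid, self.a_db,
                          shading="nearest")
        plt.colorbar(m, ax=ax, label="predicted subharmonic amplitude (dB)")
        ax.set_xlabel("hydrostatic pressure (mmHg)")
        ax.set_ylabel("effective surface tension (N/m)")
        return ax


def gas_constant(params: BubbleParams) -> float:
    """Gas-content constant ``C_ref = R_ref^3 (p_ref + 2 sigma / R_ref)``."""
    return params.r_ref**3 * (params.p_ref + 2 * params.sigma / params.r_ref)


def equilibrium_radius(p0: float, sigma: float, c_ref: float) -> float:
    """Unique positive root of ``p0 R^3 + 2 sigma R^2 - C_ref = 0``.

    Gives the equilibrium radius of the bubble after compression to ambient
    pressure ``p0`` (absolute) at shell tension ``sigma``, conserving gas
    content ``c_ref``.
    """
    if not p0 > 0:
        raise ValueError(f"p0 must be > 0, got {p0}")
    if not c_ref > 0:
        raise ValueError(f"c_ref must be > 0, got {c_ref}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")

    def poly(r: float) -> float:
        return p0 * r**3 + 2 * sigma * r**2 - c_ref

    # The Laplace term only shrinks the root, so (c_ref/p0)^(1/3) bounds it
    # from above; scale the lower bracket off the upper one.
    hi = (c_ref / p0) ** (1.0 / 3.0)
    lo = 1e-6 * hi
    if poly(lo) >= 0 or poly(hi * (1 + 1e-12)) < 0:  # pragma: no cover
        raise RuntimeError("root not bracketed; invalid equilibrium inputs")
    r0 = brentq(poly, lo, hi * (1 + 1e-12), xtol=1e-300, rtol=8.9e-16)
    assert abs(poly(r0)) <= 1e-10 * c_ref
    return r0


def linear_resonance_frequency(params: BubbleParams, r0: float,
                               p0: float) -> float:
    """Small-amplitude resonance frequency (Hz) about ``(r0, p0)``.

    Minnaert frequency generalised with the Laplace-pressure correction:
    ``omega0^2 = [3 gamma (p0 + 2 sigma/R0) - 2 sigma/R0] / (rho R0^2)``.
    """
    s = 2 * params.sigma / r0
    w2 = (3 * params.gamma * (p0 + s) - s) / (params.rho * r0**2)
    return math.sqrt(w2) / (2 * math.pi)


def simulate_rp(
    params: BubbleParams,
    eq: EquilibriumState,
    exc: Excitation,
    samples_per_cycle: int = 200,
    transient_fraction: float = 0.5,
    rtol: float = 1e-8,
) -> RadiusTrace:
    """Integrate the Rayleigh-Plesset equation from rest at equilibrium.

    ``R Rdd + 3/2 Rd^2 = (1/rho) [ (p0 + 2 sigma/R0)(R0/R)^(3 gamma)
    - 2 sigma/R - 4 mu Rd/R - p0 - (p_pp/2) sin(2 pi f t) ]``

    The returned trace is resampled onto a uniform grid of
    ``samples_per_cycle`` points per drive cycle; ``steady_start`` marks the
    end of the discarded transient (first ``transient_fraction`` of the
    simulated cycles).
    """
    if samples_per_cycle < 50:
        raise ValueError("samples_per_cycle must be >= 50")
    if not 0 <= transient_fraction < 1:
        raise ValueError("transient_fraction must be in [0, 1)")

    r0, p0 = eq.r0, eq.p0
    rho, sigma, mu, gamma = params.rho, params.sigma, params.mu, params.gamma
    p_gas0 = p0 + 2 * sigma / r0
    omega = 2 * math.pi * exc.f
    amp = exc.p_pp / 2.0

    def rhs(t, y):
        r, rd = y
        p_gas = p_gas0 * (r0 / r) ** (3 * gamma)
        p_drive = amp * math.sin(omega * t)
        acc = (
            (p_gas - 2 * sigma / r - 4 * mu * rd / r - p0 - p_drive) / rho
            - 1.5 * rd * rd
        ) / r
        return (rd, acc)

    def collapse(t, y):
        return y[0] - 0.02 * r0

    collapse.terminal = True
    collapse.direction = -1

    t_end = exc.n_cycles_total / exc.f
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        (r0, 0.0),
        method="LSODA",
        rtol=rtol,
        # absolute floors scaled to the bubble: resolve oscillations down
        # to ~1e-10 R0 so the near-linear regime stays proportional
        atol=(1e-10 * r0, 1e-10 * r0 * omega),
        dense_output=True,
        events=collapse,
        max_step=1.0 / (4 * exc.f),
    )
    if sol.status == 1:  # terminated by the collapse event
        t_fail = float(sol.t_events[0][0])
        raise BubbleCollapseError(
            f"radius collapsed below 2% of R0 at t={t_fail:.3e} s "
            "(inertial-collapse regime)", t_fail)
    if not sol.success:
        raise BubbleCollapseError(
            f"RP integration failed at t={sol.t[-1]:.3e} s: {sol.message}",
            float(sol.t[-1]))

    n = exc.n_cycles_total * samples_per_cycle
    t = np.arange(n) / (exc.f * samples_per_cycle)
    r = sol.sol(t)[0]
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise BubbleCollapseError("non-finite or non-positive radius in trace",
                                  float(t[-1]))
    return RadiusTrace(t=t, r=r, steady_start=int(round(transient_fraction * n)))


def oscillation_amplitude(trace: RadiusTrace, method: str = "half_excursion",
                          f_drive: float | None = None) -> float:
    """Scalar oscillation amplitude over the steady-state window, m.

    ``half_excursion`` (default): half the peak-to-peak radius excursion.
    ``subharmonic_line``: magnitude of the f_drive/2 Fourier component of
    R(t) (requires ``f_drive``).
    """
    rs = trace.steady_r
    if rs.size == 0:
        raise ValueError("steady-state window is empty")
    if method == "half_excursion":
        return float(rs.max() - rs.min()) / 2.0
    if method == "subharmonic_line":
        if f_drive is None:
            raise ValueError("subharmonic_line mode requires f_drive")
        ts = trace.t[trace.steady_start:]
        dt = ts[1] - ts[0]
        x = (rs - rs.mean()) * np.hanning(rs.size)
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(rs.size, dt)
        k = int(np.argmin(np.abs(freqs - f_drive / 2.0)))
        # amplitude of a Hann-windowed sinusoid: 2 |X_k| / sum(window)
        return float(2 * np.abs(spec[k]) / np.hanning(rs.size).sum())
    raise ValueError(f"unknown amplitude method {method!r}")


def predicted_amplitude(dr: float, dr_ref: float, p0_abs: float,
                        p_ref: float = ATM_PA) -> float:
    """Predicted subharmonic amplitude in dB.

    ``A = 27 + 20 log10( (dr/dr_ref) * (p_ref/p0_abs) )``; the 27-dB anchor
    is the signal level at the reference operating point (dr = dr_ref,
    p0 = p_ref).  A non-positive oscillation amplitude (silent bubble)
    returns -inf with a warning.
    """
    if not dr_ref > 0:
        raise ValueError(f"dr_ref must be > 0, got {dr_ref}")
    if not p0_abs > 0:
        raise ValueError(f"p0_abs must be > 0, got {p0_abs}")
    if dr <= 0:
        warnings.warn("non-positive oscillation amplitude: silent bubble",
                      stacklevel=2)
        return float("-inf")
    return 27.0 + 20.0 * math.log10((dr / dr_ref) * (p_ref / p0_abs))


def amplitude_surface(
    params: BubbleParams,
    exc: Excitation,
    p_grid_mmhg,
    sigma_grid,
    samples_per_cycle: int = 200,
    amplitude_method: str = "half_excursion",
) -> AmplitudeSurface:
    """Predicted-amplitude map over hydrostatic pressure x surface tension.

    For each cell: re-solve the gas-conservation cubic for R0 at the cell's
    absolute pressure ``p_ref + p_gauge`` and tension, integrate the RP
    equation, measure the steady oscillation amplitude, and map it through
    the dB prediction.  The reference amplitude ``dr_ref`` is taken at
    (0 mmHg gauge, sigma = 0.07 N/m), the elastic shell at ambient pressure,
    so that cell evaluates to exactly 27 dB.  Cells where the integration
    collapses are NaN (logged).
    """
    p_grid_mmhg = np.atleast_1d(np.asarray(p_grid_mmhg, dtype=float))
    sigma_grid = np.atleast_1d(np.asarray(sigma_grid, dtype=float))
    if p_grid_mmhg.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be non-empty")

    c_ref = gas_constant(params)

    def cell_amplitude(p_gauge_mmhg: float, sigma: float) -> float:
        p_abs = params.p_ref + mmhg_to_pa(p_gauge_mmhg)
        r0 = equilibrium_radius(p_abs, sigma, c_ref)
        cell_params = replace(params, sigma=sigma)
        trace = simulate_rp(cell_params,
                            EquilibriumState(p0=p_abs, r0=r0, c_ref=c_ref),
                            exc, samples_per_cycle=samples_per_cycle)
        return oscillation_amplitude(trace, method=amplitude_method,
                                     f_drive=exc.f)

    dr_ref = cell_amplitude(0.0, SIGMA_AIR_WATER)
    a = np.full((sigma_grid.size, p_grid_mmhg.size), np.nan)
    for i, sigma in enumerate(sigma_grid):
        for j, p in enumerate(p_grid_mmhg):
            try:
                dr = cell_amplitude(p, sigma)
            except BubbleCollapseError as exc_err:
                log.warning("surface cell (p=%g mmHg, sigma=%g) failed: %s",
                            p, sigma, exc_err)
                continue
            a[i, j] = predicted_amplitude(
                dr, dr_ref, params.p_ref + mmhg_to_pa(p), params.p_ref)
    return AmplitudeSurface(p0_grid_mmhg=p_grid_mmhg, sigma_grid=sigma_grid,
                            a_db=a, dr_ref=dr_ref)


class RayleighPlessetModel:
    """Model object bundling bubble parameters with an acoustic drive.

    Thin statsmodels-style facade over the module functions:

    >>> m = RayleighPlessetModel(BubbleParams(), Excitation(f=1e6))
    >>> trace = m.simulate(p_gauge_mmhg=100.0)
    >>> m.oscillation_amplitude(trace)  # doctest: +SKIP
    """

    def __init__(self, params: BubbleParams | None = None,
                 excitation: Excitation | None = None):
        self.params = params if params is not None else BubbleParams()
        self.excitation = excitation if excitation is not None else Excitation()
        self.c_ref = gas_constant(self.params)

    def equilibrium(self, p_gauge_mmhg: float = 0.0,
                    sigma: float | None = None) -> EquilibriumState:
        sigma = self.params.sigma if sigma is None else sigma
        p_abs = self.params.p_ref + mmhg_to_pa(p_gauge_mmhg)
        r0 = equilibrium_radius(p_abs, sigma, self.c_ref)
        return EquilibriumState(p0=p_abs, r0=r0, c_ref=self.c_ref)

    def simulate(self, p_gauge_mmhg: float = 0.0, sigma: float | None = None,
                 **kwargs) -> RadiusTrace:
        sigma = self.params.sigma if sigma is None else sigma
        eq = self.equilibrium(p_gauge_mmhg, sigma)
        return simulate_rp(replace(self.params, sigma=sigma), eq,
                           self.excitation, **kwargs)

    def oscillation_amplitude(self, trace: RadiusTrace,
                              method: str = "half_excursion") -> float:
        return oscillation_amplitude(trace, method=method,
                                     f_drive=self.excitation.f)

    def amplitude_surface(self, p_grid_mmhg, sigma_grid,
                          **kwargs) -> AmplitudeSurface:
        return amplitude_surface(self.params, self.excitation, p_grid_mmhg,
                                 sigma_grid, **kwargs)
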