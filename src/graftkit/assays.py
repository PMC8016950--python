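"""Binding-assay models: ELISA, SPR single-cycle kinetics, saturation, Lindmo.

Four quantifications used to validate an engineered antibody fragment:

* **ELISA equilibrium curve** — signal vs analyte concentration,
  ``y = background + a_max * c / (k_d + c)`` (plate-immobilized antigen,
  no ligand depletion).
* **SPR single-cycle kinetics** — a 1:1 Langmuir binding model,
  ``dR/dt = k_on * C(t) * (r_max - R) - k_off * R`` integrated across
  sequential analyte injections within one cycle and fitted globally;
  ``K_D = k_off / k_on`` by construction.
* **Saturation binding** — specific binding ``B = b_max * c / (k_d + c)``
  on whole cells.
* **Lindmo immunoreactive fraction** — double-inverse plot: regression of
  total/bound against 1/[cells]; extrapolation to infinite antigen excess
  gives the immunoreactive fraction as 1/intercept.

Nonlinear fits use damped least squares with positivity bounds
(scipy ``curve_fit``/``least_squares``); simulators are seeded and record
the true parameters in the dataset provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats


class FitError(RuntimeError):
    pass


@dataclass
class AssayDataset:
    """x/y series plus provenance (measured, or simulated with known truth)."""

    x: np.ndarray
    y: np.ndarray
    kind: str                      # elisa | spr | saturation | lindmo
    provenance: dict = field(default_factory=lambda: {"source": "measured"})
    schedule: list | None = None   # SPR: [(t_start, t_end, concentration_M)]

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")


@dataclass(frozen=True)
class ElisaFit:
    k_d: float
    a_max: float
    background: float
    k_d_stderr: float
    covariance: np.ndarray
    plateau_reached: bool

    def as_dict(self) -> dict:
        return {"k_d": self.k_d, "a_max": self.a_max, "background": self.background,
                "k_d_stderr": self.k_d_stderr, "plateau_reached": self.plateau_reached}


@dataclass(frozen=True)
class KineticFit:
    k_on: float
    k_off: float
    r_max: float
    residual_rms: float
    k_off_identifiable: bool = True

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on


@dataclass(frozen=True)
class LindmoResult:
    immunoreactive_fraction: float
    intercept: float
    slope: float
    r_squared: float
    flagged: bool  # fraction implausibly above 1 (tolerance 1.05)


@dataclass(frozen=True)
class SaturationFit:
    k_d: float
    b_max: float
    k_d_stderr: float


# --- ELISA ------------------------------------------------------------------

def _langmuir(c, k_d, a_max, background):
    return background + a_max * c / (k_d + c)


def fit_elisa(data: AssayDataset) -> ElisaFit:
    """Fit the equilibrium binding isotherm to an ELISA dilution series.

    Initial K_D is the concentration nearest half-maximal signal.  A curve
    whose top point is still >15% below the fitted plateau is flagged as
    lacking a plateau.  Degenerate (constant) input raises :class:`FitError`.
    """
    c, y = data.x, data.y
    if len(np.unique(c)) < 5:
        raise FitError("need at least 5 distinct concentrations")
    if np.ptp(y) <= 0 or np.ptp(y) < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        raise FitError("signal is constant: K_D not identifiable")
    y0, y1 = float(y.min()), float(y.max())
    half = y0 + 0.5 * (y1 - y0)
    k0 = float(c[np.argmin(np.abs(y - half))])
    p0 = (max(k0, 1e-15), max(y1 - y0, 1e-12), y0)
    try:
        popt, pcov = optimize.curve_fit(
            _langmuir, c, y, p0=p0,
            bounds=([1e-18, 1e-18, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"ELISA fit did not converge: {exc}") from exc
    k_d, a_max, background = (float(v) for v in popt)
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    plateau = float(c.max()) >= 3.0 * k_d
    return ElisaFit(k_d, a_max, background, stderr, pcov, plateau)


def simulate_elisa(k_d: float, a_max: float, background: float,
                   concentrations: Sequence[float], noise_cv: float = 0.0,
                   seed: int = 0) -> AssayDataset:
    """Simulate an ELISA series with multiplicative Gaussian noise (seeded)."""
    if min(k_d, a_max) <= 0:
        raise ValueError("parameters must be positive")
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    y = _langmuir(c, k_d, a_max, background)
    if noise_cv > 0:
        y = y * (1.0 + noise_cv * rng.standard_normal(len(c)))
    return AssayDataset(c, y, "elisa", provenance={
        "source": "simulated", "seed": seed, "noise_cv": noise_cv,
        "truth": {"k_d": k_d, "a_max": a_max, "background": background}})


# --- SPR single-cycle kinetics ----------------------------------------------

def integrate_binding(times: np.ndarray, schedule: list, k_on: float,
                      k_off: float, r_max: float, r0: float = 0.0,
                      max_step: float = 0.1) -> np.ndarray:
    """Integrate the 1:1 binding ODE across injection segments (RK4).

    ``schedule`` lists ``(t_start, t_end, concentration)`` segments; the
    analyte concentration is piecewise constant (0 during dissociation) and
    the response is continuous across segment boundaries.  Fixed-step
    fourth-order Runge-Kutta with step <= ``max_step`` seconds.
    """
    times = np.asarray(times, dtype=float)

    def conc(t: float) -> float:
        for t0, t1, c in schedule:
            if t0 <= t < t1:
                return c
        return 0.0

    def f(t, r):
        return k_on * conc(t) * (r_max - r) - k_off * r

    out = np.empty_like(times)
    r = r0
    t = float(times[0])
    out[0] = r
    for i in range(1, len(times)):
        t_next = float(times[i])
        span = t_next - t
        nstep = max(1, int(math.ceil(span / max_step)))
        h = span / nstep
        for k in range(nstep):
            tk = t + k * h
            k1 = f(tk, r)
            k2 = f(tk + h / 2, r + h / 2 * k1)
            k3 = f(tk + h / 2, r + h / 2 * k2)
            k4 = f(tk + h, r + h * k3)
            r = r + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t_next
        out[i] = r
    return out


def association_closed_form(t, c, k_on, k_off, r_max):
    """Single-association analytic solution (oracle for the integrator)."""
    kobs = k_on * c + k_off
    r_eq = r_max * k_on * c / kobs
    return r_eq * (1.0 - np.exp(-kobs * np.asarray(t, dtype=float)))


def simulate_sck(schedule: list, t_end: float, k_on: float, k_off: float,
                 r_max: float, dt: float = 1.0, noise_sd: float = 0.0,
                 seed: int = 0) -> AssayDataset:
    """Simulate a single-cycle SPR trace with additive Gaussian noise."""
    times = np.arange(0.0, t_end + dt / 2, dt)
    r = integrate_binding(times, schedule, k_on, k_off, r_max)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        r = r + noise_sd * rng.standard_normal(len(r))
    return AssayDataset(times, r, "spr", schedule=schedule, provenance={
        "source": "simulated", "seed": seed, "noise_sd": noise_sd,
        "truth": {"k_on": k_on, "k_off": k_off, "r_max": r_max}})


def fit_sck_spr(data: AssayDataset, schedule: list | None = None,
                p0: tuple | None = None) -> KineticFit:
    """Global 1:1 fit of a single-cycle SPR trace.

    Optimizes log-parameters (positivity by construction) with damped least
    squares over the whole trace.  ``k_off`` is flagged non-identifiable
    when the trace shows no measurable decay information (fitted k_off
    hitting the lower bound).
    """
    schedule = schedule or data.schedule
    if not schedule:
        raise FitError("an injection schedule is required")
    t, y = data.x, data.y
    span = float(y.max() - y.min())
    if span <= 0:
        raise FitError("flat trace: kinetics not identifiable")
    c_max = max(c for _, _, c in schedule if c > 0)
    if p0 is None:
        p0 = (1e5, 1e-3, float(y.max()) * 1.2)
    lp0 = np.log(np.asarray(p0))

    def residual(lp):
        k_on, k_off, r_max = np.exp(lp)
        with np.errstate(over="ignore", invalid="ignore"):
            model = integrate_binding(t, schedule, k_on, k_off, r_max)
        bad = ~np.isfinite(model)
        if bad.any():  # runaway exploratory step: steer back with finite values
            model = np.where(bad, 1e4 * (1.0 + np.abs(y).max()), model)
        return model - y

    sol = optimize.least_squares(residual, lp0, method="trf", max_nfev=400)
    if not sol.success:
        raise FitError(f"SPR fit did not converge: {sol.message}")
    k_on, k_off, r_max = (float(v) for v in np.exp(sol.x))
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    # k_off below the resolvable scale of the trace -> not identifiable
    identifiable = k_off * float(t[-1] - t[0]) > 1e-3
    return KineticFit(k_on, k_off, r_max, rms, k_off_identifiable=identifiable)


def default_sck_schedule(concentrations: Sequence[float], t_assoc: float = 120.0,
                         t_dissoc_final: float = 600.0) -> tuple:
    """Build a single-cycle schedule: sequential injections, then dissociation.

    Returns ``(schedule, t_end)``.
    """
    schedule = []
    t = 0.0
    for c in concentrations:
        schedule.append((t, t + t_assoc, float(c)))
        t += t_assoc
    return schedule, t + t_dissoc_final


# --- saturation binding -----------------------------------------------------

def fit_saturation(data: AssayDataset) -> SaturationFit:
    """Fit specific binding B = b_max * c / (k_d + c)."""
    c, y = data.x, data.y
    if len(np.unique(c)) < 5:
        raise FitError("need at least 5 concentrations")
    if np.ptp(y) <= 0:
        raise FitError("signal is constant: K_D not identifiable")
    half = 0.5 * float(y.max())
    k0 = float(c[np.argmin(np.abs(y - half))])
    try:
        popt, pcov = optimize.curve_fit(
            lambda cc, k_d, b_max: b_max * cc / (k_d + cc), c, y,
            p0=(max(k0, 1e-15), float(y.max())),
            bounds=([1e-18, 1e-18], [np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"saturation fit did not converge: {exc}") from exc
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    return SaturationFit(float(popt[0]), float(popt[1]), stderr)


def simulate_saturation(k_d: float, b_max: float, concentrations: Sequence[float],
                        noise_cv: float = 0.0, seed: int = 0) -> AssayDataset:
    """Simulate a saturation binding series (multiplicative noise, seeded)."""
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    y = b_max * c / (k_d + c)
    if noise_cv > 0:
        y = y * (1.0 + noise_cv * rng.standard_normal(len(c)))
    return AssayDataset(c, y, "saturation", provenance={
        "source": "simulated", "seed": seed, "noise_cv": noise_cv,
        "truth": {"k_d": k_d, "b_max": b_max}})


# --- Lindmo -----------------------------------------------------------------

def lindmo_fit(data: AssayDataset) -> LindmoResult:
    """Immunoreactive fraction by the double-inverse (Lindmo) plot.

    ``x`` is cell concentration, ``y`` the bound fraction of added tracer.
    Replicate x values are averaged before the regression of total/bound
    against 1/[cells]; the immunoreactive fraction is 1/intercept at
    infinite antigen excess.
    """
    x, y = data.x, data.y
    if np.any(x <= 0) or np.any(y <= 0) or np.any(y >= 1):
        raise FitError("cell concentrations must be positive and bound fractions in (0,1)")
    # average duplicates
    ux = np.unique(x)
    if len(ux) < 4:
        raise FitError("need at least 4 distinct cell concentrations")
    uy = np.array([float(np.mean(y[x == v])) for v in ux])
    inv_x = 1.0 / ux
    inv_y = 1.0 / uy  # total/bound
    res = stats.linregress(inv_x, inv_y)
    if res.intercept <= 0:
        raise FitError(f"non-positive intercept {res.intercept:.3g}: fraction undefined")
    frac = 1.0 / res.intercept
    return LindmoResult(immunoreactive_fraction=frac, intercept=float(res.intercept),
                        slope=float(res.slope), r_squared=float(res.rvalue ** 2),
                        flagged=frac > 1.05)


def simulate_lindmo(fraction: float, k_d: float, cells: Sequence[float],
                    antigen_per_cell: float = 1e6, noise_cv: float = 0.0,
                    seed: int = 0) -> AssayDataset:
    """Simulate a Lindmo cell-binding series.

    Bound fraction of an immunoreactive tracer at cell concentration N
    (cells/L) follows ``b = f * A / (A + K_D)`` with antigen concentration
    ``A = N * antigen_per_cell / N_Avogadro`` (antigen excess over tracer).
    The default 1e6 antigens/cell is typical for an overexpressed surface
    antigen and places A around a ~15 nM K_D for cell concentrations of
    1e9-1e11 cells/L, the regime where the double-inverse plot is stable.
    Fractional noise is multiplicative Gaussian, seeded.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n_av = 6.02214076e23
    cells_arr = np.asarray(cells, dtype=float)
    antigen = cells_arr * antigen_per_cell / n_av
    bound = fraction * antigen / (antigen + k_d)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        bound = bound * (1.0 + noise_cv * rng.standard_normal(len(bound)))
    bound = np.clip(bound, 1e-9, 1 - 1e-9)
    return AssayDataset(cells_arr, bound, "lindmo", provenance={
        "source": "simulated", "seed": seed, "noise_cv": noise_cv,
        "truth": {"fraction": fraction, "k_d": k_d,
                  "antigen_per_cell": antigen_per_cell}})
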