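"""Solid–liquid and liquid–liquid equilibria of binary API–polymer systems.

The solubility curve follows from equating the chemical potential of the
crystalline API with that of the dissolved API,

    ln(x_API γ_API) = −Δfus g(T) / (R T),

where Δfus g is the Gibbs-energy difference between the pure supercooled
liquid and the crystal, evaluated from T_m, Δfus h and a (possibly
T-linear) Δfus c_p.  Amorphous–amorphous demixing is located by the
isoactivity condition x_i^L1 γ_i^L1 = x_i^L2 γ_i^L2 for both components,
solved either directly (2×2 root find) or by the alternating-tangents
construction on the mixing Gibbs energy.  Phase diagrams collect the SLE
curve, binodal and spinodal branches, UCST/LCST and stability flags, all
reported in weight fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import optimize

from .activity_model import ActivityResult, Component, ModelConfig, lngamma_total
from .constants import R_J

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryState",
    "PhaseDiagram",
    "BinarySystem",
    "CosmoSacSystem",
    "MargulesSystem",
    "LleConvergenceError",
    "delta_fus_g",
    "solve_sle",
    "solve_lle",
    "spinodal",
    "build_phase_diagram",
    "x_to_w",
    "w_to_x",
]

_X_FLOOR = 1e-12


class LleConvergenceError(RuntimeError):
    """LLE solver failure; carries method, temperature and last residuals."""

    def __init__(self, method: str, t: float, residuals):
        super().__init__(
            f"LLE {method} solver failed to converge at T = {t:.2f} K "
            f"(last residuals {residuals})"
        )
        self.method = method
        self.t = t
        self.residuals = residuals


# ---------------------------------------------------------------------------
# composition handling
# ---------------------------------------------------------------------------

def x_to_w(x_api: float, m_api: float, m_poly: float) -> float:
    """Mole fraction of API → weight fraction of API."""
    num = x_api * m_api
    return num / (num + (1.0 - x_api) * m_poly)

def w_to_x(w_api: float, m_api: float, m_poly: float) -> float:
    """Weight fraction of API → mole fraction of API."""
    num = w_api / m_api
    return num / (num + (1.0 - w_api) / m_poly)


@dataclass(frozen=True)
class BinaryState:
    """A temperature–composition point of the binary (API, polymer)."""

    t: float
    x: tuple[float, float]
    w: tuple[float, float]

    def __post_init__(self) -> None:
        for vec in (self.x, self.w):
            if abs(sum(vec) - 1.0) > 1e-12:
                raise ValueError("composition vectors must sum to 1")

    @classmethod
    def from_x(cls, t: float, x_api: float, m_api: float, m_poly: float) -> "BinaryState":
        w = x_to_w(x_api, m_api, m_poly)
        return cls(t, (x_api, 1.0 - x_api), (w, 1.0 - w))


# ---------------------------------------------------------------------------
# systems: anything that can produce ln γ for both components
# ---------------------------------------------------------------------------

@runtime_checkable
class BinarySystem(Protocol):
    """Minimal interface the equilibrium solvers need."""

    api: Component
    polymer: Component

    def lngamma(self, x_api: float, t: float) -> tuple[float, float]:
        """(ln γ_API, ln γ_polymer) at mole fraction x_api and T."""
        ...


@dataclass
class CosmoSacSystem:
    """Binary system evaluated through the full activity model."""

    api: Component
    polymer: Component
    config: ModelConfig = field(default_factory=ModelConfig)

    def lngamma(self, x_api: float, t: float) -> tuple[float, float]:
        res = self.activity(x_api, t)
        return float(res.total[0]), float(res.total[1])

    def activity(self, x_api: float, t: float) -> ActivityResult:
        x = np.array([x_api, 1.0 - x_api])
        return lngamma_total([self.api, self.polymer], x, t, self.config)


@dataclass
class MargulesSystem:
    """Analytic symmetric system: ln γ1 = A(T) x2², ln γ2 = A(T) x1²."""

    a: float | Callable[[float], float]
    api: Component = None
    polymer: Component = None

    def __post_init__(self) -> None:
        if self.api is None:
            self.api = Component(name="api", m=100.0)
        if self.polymer is None:
            self.polymer = Component(name="poly", m=100.0)

    def a_at(self, t: float) -> float:
        return self.a(t) if callable(self.a) else self.a

    def lngamma(self, x_api: float, t: float) -> tuple[float, float]:
        a = self.a_at(t)
        x2 = 1.0 - x_api
        return a * x2 * x2, a * x_api * x_api


# ---------------------------------------------------------------------------
# SLE
# ---------------------------------------------------------------------------

def delta_fus_g(api: Component | object, t: float) -> float:
    """Fusion Gibbs energy of the pure API in kJ/mol at temperature T.

    Δfus g(T) = Δfus h (1 − T/T_m) − ∫_T^{T_m} Δc_p dT' + T ∫_T^{T_m} (Δc_p/T') dT'
    with Δc_p = a + b T' integrated analytically.  Equals 0 exactly at T_m.
    """
    fusion = getattr(api, "fusion", None) or api
    if not hasattr(fusion, "tm"):
        raise ValueError("component carries no fusion properties")
    if t <= 0:
        raise ValueError("temperature must be positive")
    tm, dh = fusion.tm, fusion.dh_fus * 1000.0  # J/mol
    a, b = fusion.dcp_a, fusion.dcp_b
    int_dcp = a * (tm - t) + 0.5 * b * (tm * tm - t * t)
    int_dcp_over_t = a * np.log(tm / t) + b * (tm - t)
    dg = dh * (1.0 - t / tm) - int_dcp + t * int_dcp_over_t
    return dg / 1000.0  # kJ/mol


def solve_sle(
    system: BinarySystem,
    t: float,
    residual_tol: float = 1e-10,
) -> float | None:
    """Solve ln x + ln γ_API(x) + Δfus g/(RT) = 0 for x_API in (0, 1].

    Returns the saturation mole fraction, or None when no root exists at
    this temperature ("no solubility").  When several roots exist the one
    with the largest x (closest to ideal) is returned with a warning.
    """
    dg = delta_fus_g(system.api, t) * 1000.0  # J/mol
    rhs = dg / (R_J * t)

    def f(x: float) -> float:
        return np.log(x) + system.lngamma(x, t)[0] + rhs

    # bracket scan, log-spaced toward x -> 0 plus a linear sweep
    grid = np.unique(np.concatenate([
        np.logspace(np.log10(_X_FLOOR), -1, 25),
        np.linspace(0.1, 1.0, 46),
    ]))
    values = np.array([f(x) for x in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        lo, hi = values[i], values[i + 1]
        if lo == 0.0:
            roots.append(grid[i])
        elif lo * hi < 0.0:
            roots.append(float(optimize.brentq(
                f, grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16, maxiter=200
            )))
    if values[-1] == 0.0:
        roots.append(grid[-1])
    if not roots:
        logger.info("no solubility at T = %.2f K (no root of the SLE equation)", t)
        return None
    if len(roots) > 1:
        logger.warning(
            "multiple SLE roots at T = %.2f K: %s; keeping the largest", t, roots
        )
    x = max(roots)
    if abs(f(x)) > residual_tol:
        logger.warning("SLE residual %.2e exceeds %.0e at T = %.2f", f(x), residual_tol, t)
    return x


# ---------------------------------------------------------------------------
# mixing Gibbs energy helpers
# ---------------------------------------------------------------------------

def _ln_activities(system: BinarySystem, x: float, t: float) -> tuple[float, float]:
    x = min(max(x, _X_FLOOR), 1.0 - _X_FLOOR)
    g1, g2 = system.lngamma(x, t)
    return np.log(x) + g1, np.log(1.0 - x) + g2


def gmix(system: BinarySystem, x: float, t: float) -> float:
    """Reduced molar mixing Gibbs energy Δg_mix/RT at x_API = x."""
    x = min(max(x, _X_FLOOR), 1.0 - _X_FLOOR)
    la1, la2 = _ln_activities(system, x, t)
    return x * la1 + (1.0 - x) * la2


def dgmix_dx(system: BinarySystem, x: float, t: float) -> float:
    """d(Δg_mix/RT)/dx = ln a1 − ln a2 (by the Gibbs–Duhem relation)."""
    la1, la2 = _ln_activities(system, x, t)
    return la1 - la2


def d2gmix_dx2(system: BinarySystem, x: float, t: float, h: float = 1e-5) -> float:
    """Second derivative of Δg_mix/RT via central differences of ln a."""
    h = min(h, 0.5 * x, 0.5 * (1.0 - x))
    return (dgmix_dx(system, x + h, t) - dgmix_dx(system, x - h, t)) / (2.0 * h)


# ---------------------------------------------------------------------------
# LLE
# ---------------------------------------------------------------------------

def _curvature_scan(system: BinarySystem, t: float, n: int = 200) -> np.ndarray:
    """Grid of compositions with the local sign of the g'' proxy."""
    xs = np.linspace(0.0, 1.0, n + 2)[1:-1]
    slope = np.array([dgmix_dx(system, x, t) for x in xs])
    return xs, np.diff(slope)


def _initial_tie_line(system: BinarySystem, t: float, n: int = 200):
    """Initial binodal guess bracketing the concave (unstable) region."""
    xs, dslope = _curvature_scan(system, t, n)
    unstable = np.where(dslope < 0.0)[0]
    if unstable.size == 0:
        return None
    left = xs[unstable[0]]
    right = xs[unstable[-1] + 1]
    # start from the midpoints between the spinodal-ish window and the edges
    return 0.5 * left, 0.5 * (right + 1.0)


def _solve_lle_direct(
    system: BinarySystem, t: float, guess: tuple[float, float], tol: float
) -> tuple[float, float]:
    def residuals(z: np.ndarray) -> np.ndarray:
        xa = 1.0 / (1.0 + np.exp(-z[0]))  # logistic keeps x in (0, 1)
        xb = 1.0 / (1.0 + np.exp(-z[1]))
        la1a, la2a = _ln_activities(system, xa, t)
        la1b, la2b = _ln_activities(system, xb, t)
        return np.array([la1a - la1b, la2a - la2b])

    z0 = np.array([np.log(g / (1.0 - g)) for g in guess])
    sol = optimize.root(residuals, z0, method="hybr", tol=1e-13)
    res = residuals(sol.x)
    if not sol.success and np.max(np.abs(res)) > tol:
        raise LleConvergenceError("direct", t, res)
    xa = float(1.0 / (1.0 + np.exp(-sol.x[0])))
    xb = float(1.0 / (1.0 + np.exp(-sol.x[1])))
    return xa, xb


def _tangent_touch(
    system: BinarySystem, t: float, x_from: float, lo: float, hi: float
) -> float | None:
    """x in [lo, hi] where the tangent drawn from (x_from, g(x_from)) touches."""
    g0 = gmix(system, x_from, t)

    def f(x: float) -> float:
        return dgmix_dx(system, x, t) - (gmix(system, x, t) - g0) / (x - x_from)

    xs = np.linspace(lo, hi, 60)
    vals = [f(x) for x in xs]
    for i in range(len(xs) - 1):
        if vals[i] * vals[i + 1] < 0.0:
            return float(optimize.brentq(f, xs[i], xs[i + 1], xtol=1e-14))
    return None


def _solve_lle_alternating(
    system: BinarySystem, t: float, guess: tuple[float, float], tol: float,
    maxiter: int = 500,
) -> tuple[float, float]:
    """Alternating-tangents construction on the Δg_mix curve.

    From the current right-phase point a line is drawn that passes through
    it and is tangent to the left convex lobe; the touch point becomes the
    new left phase, and vice versa.  Each tangency search is restricted to
    the convex lobe on the far side of the concave window so the spurious
    inflection tangencies are excluded.
    """
    xs, dslope = _curvature_scan(system, t)
    unstable = np.where(dslope < 0.0)[0]
    if unstable.size == 0:
        raise LleConvergenceError("alternating", t, (np.nan, np.nan))
    left_sp = float(xs[unstable[0]])
    right_sp = float(xs[unstable[-1] + 1])

    xa, xb = guess
    res = (np.inf, np.inf)
    for _ in range(maxiter):
        xa_new = _tangent_touch(system, t, xb, _X_FLOOR * 10, left_sp)
        if xa_new is None:
            break
        xb_new = _tangent_touch(system, t, xa_new, right_sp, 1.0 - _X_FLOOR * 10)
        if xb_new is None:
            break
        xa, xb = xa_new, xb_new
        la1a, la2a = _ln_activities(system, xa, t)
        la1b, la2b = _ln_activities(system, xb, t)
        res = (la1a - la1b, la2a - la2b)
        if max(abs(res[0]), abs(res[1])) < tol:
            return xa, xb
    raise LleConvergenceError("alternating", t, res)


def solve_lle(
    system: BinarySystem,
    t: float,
    method: str = "direct",
    guess: tuple[float, float] | None = None,
    isoactivity_tol: float = 1e-8,
) -> tuple[float, float] | None:
    """Binodal compositions (x_API^L1, x_API^L2) at T, or None if one phase.

    Both liquid phases satisfy the isoactivity condition for API and
    polymer; the trivial root x^L1 = x^L2 is rejected.
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    if guess is None:
        guess = _initial_tie_line(system, t)
        if guess is None:
            return None
    if method == "direct":
        xa, xb = _solve_lle_direct(system, t, guess, isoactivity_tol)
    elif method == "alternating":
        xa, xb = _solve_lle_alternating(system, t, guess, isoactivity_tol)
    else:
        raise ValueError(f"unknown LLE method {method!r}")
    if abs(xa - xb) < 1e-5:
        return None
    la1a, la2a = _ln_activities(system, xa, t)
    la1b, la2b = _ln_activities(system, xb, t)
    res = max(abs(la1a - la1b), abs(la2a - la2b))
    if res > isoactivity_tol:
        raise LleConvergenceError(method, t, (la1a - la1b, la2a - la2b))
    lo, hi = sorted((xa, xb))
    return float(lo), float(hi)


def spinodal(
    system: BinarySystem, t: float, n: int = 400
) -> tuple[float, float] | None:
    """Roots of ∂²(Δg_mix/RT)/∂x² = 0, or None when the curve is convex."""
    xs = np.linspace(1e-6, 1.0 - 1e-6, n)
    vals = np.array([d2gmix_dx2(system, x, t) for x in xs])
    roots: list[float] = []
    for i in range(n - 1):
        if vals[i] * vals[i + 1] < 0.0:
            roots.append(float(optimize.brentq(
                lambda x: d2gmix_dx2(system, x, t), xs[i], xs[i + 1], xtol=1e-12
            )))
    if not roots:
        return None
    return min(roots), max(roots)


# ---------------------------------------------------------------------------
# phase diagram assembly
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """SLE curve, binodal/spinodal branches and critical-point summary."""

    sle: list[tuple[float, float]]                       # (T, w_API)
    binodal: list[tuple[float, float, float]]            # (T, w^L1, w^L2)
    spinodal: list[tuple[float, float, float]]           # (T, w_lo, w_hi)
    ucst: float | None = None
    lcst: float | None = None
    aaps: bool = False
    metastable: bool | None = None


def _has_instability(system: BinarySystem, t: float, n: int = 101) -> bool:
    """True if Δg_mix has a concave region at T (min g'' < 0).

    A coarse scan is refined by a bounded minimization so that the narrow
    unstable window just below a critical point is not missed.
    """
    xs = np.linspace(1e-6, 1.0 - 1e-6, n)
    vals = np.array([d2gmix_dx2(system, x, t) for x in xs])
    if vals.min() < 0.0:
        return True
    i = int(np.argmin(vals))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, n - 1)]
    res = optimize.minimize_scalar(
        lambda x: d2gmix_dx2(system, x, t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return bool(res.fun < 0.0)


def _bracket_critical(
    system: BinarySystem,
    t_with: float,
    t_without: float,
    tol: float = 0.01,
) -> float:
    """Bisect the temperature where the two-phase split disappears."""
    while abs(t_without - t_with) > tol:
        mid = 0.5 * (t_with + t_without)
        if _has_instability(system, mid):
            t_with = mid
        else:
            t_without = mid
    return 0.5 * (t_with + t_without)


def build_phase_diagram(
    system: BinarySystem,
    t_grid: Sequence[float],
    lle_method: str = "direct",
) -> PhaseDiagram:
    """Assemble SLE + LLE information over a monotone temperature grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a monotonically increasing 1-D grid")
    m_api, m_poly = system.api.m, system.polymer.m
    has_fusion = getattr(system.api, "fusion", None) is not None

    sle_pts: list[tuple[float, float]] = []
    if has_fusion:
        for t in t_grid:
            if t > system.api.fusion.tm:
                continue
            x = solve_sle(system, float(t))
            if x is not None:
                sle_pts.append((float(t), x_to_w(x, m_api, m_poly)))

    binodal_pts: list[tuple[float, float, float]] = []
    binodal_x: list[tuple[float, float, float]] = []
    spinodal_pts: list[tuple[float, float, float]] = []
    split_flags: list[bool] = []
    guess = None
    for t in t_grid:
        tie = None
        try:
            tie = solve_lle(system, float(t), method=lle_method, guess=guess)
        except LleConvergenceError:
            logger.warning("LLE solver failure at T = %.2f K; point skipped", t)
        split_flags.append(tie is not None)
        if tie is not None:
            guess = tie  # continuation in T
            binodal_x.append((float(t), *tie))
            binodal_pts.append((
                float(t),
                x_to_w(tie[0], m_api, m_poly),
                x_to_w(tie[1], m_api, m_poly),
            ))
            sp = spinodal(system, float(t))
            if sp is not None:
                spinodal_pts.append((
                    float(t),
                    x_to_w(sp[0], m_api, m_poly),
                    x_to_w(sp[1], m_api, m_poly),
                ))
        else:
            guess = None

    ucst = lcst = None
    if any(split_flags):
        idx = [i for i, flag in enumerate(split_flags) if flag]
        first, last = idx[0], idx[-1]
        if last + 1 < len(t_grid):
            ucst = _bracket_critical(
                system, float(t_grid[last]), float(t_grid[last + 1])
            )
        if first > 0:
            lcst = _bracket_critical(
                system, float(t_grid[first]), float(t_grid[first - 1])
            )

    metastable = None
    if any(split_flags) and sle_pts:
        sle_t = np.array([p[0] for p in sle_pts])
        sle_w = np.array([p[1] for p in sle_pts])
        below = []
        for t, w1, _w2 in binodal_pts:
            w_sat = float(np.interp(t, sle_t, sle_w))
            below.append(w1 >= w_sat)
        metastable = all(below)

    return PhaseDiagram(
        sle=sle_pts,
        binodal=binodal_pts,
        spinodal=spinodal_pts,
        ucst=ucst,
        lcst=lcst,
        aaps=any(split_flags),
        metastable=metastable,
    )
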