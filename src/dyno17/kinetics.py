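"""Three-phase H₂¹⁷O kinetic model: forward simulation, fitting, fit scoring.

The inhalation experiment has a baseline phase (room air), an inhalation
phase of enriched ¹⁷O₂ gas between ``t_a`` and ``t_b``, and a decay phase
after the switch back to room air. Metabolised ¹⁷O-labelled water makes the
tissue concentration C(t) rise during inhalation and wash out afterwards.
The model used here is the linear ordinary differential equation

    dC/dt = 2·alpha·u(t)·cmro2 + k_g·X(t) − k_l·(C − c0)

with u(t) = 1 on [t_a, t_b] and 0 otherwise, and a recirculated body-water
excess X(t) that ramps up linearly during inhalation and decays with the
washout rate afterwards:

    X(t) = 0                                   t < t_a
    X(t) = t − t_a                             t_a ≤ t ≤ t_b
    X(t) = (t_b − t_a)·exp(−k_l·(t − t_b))     t > t_b

The three terms are metabolic production (2·alpha·CMRO₂; the factor 2
counts the two ¹⁷O-water molecules produced per ¹⁷O₂ molecule consumed at
gas enrichment fraction alpha), gain from recirculating labelled body
water, and first-order loss toward the baseline concentration c0. The
equation is solved in closed form per phase; see :func:`at_forward`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .core import SignalCurve

__all__ = ["ATParams", "FitResult", "at_forward", "at_fit", "adjusted_r2"]

#: below this washout rate (1/min) the closed form switches to a series
#: expansion in k_l to avoid cancellation; keeps double-precision error <1e-9
K_SMALL = 1e-8

#: free parameters fitted by default (alpha, t_a, t_b are fixed by design)
DEFAULT_FREE = ("cmro2", "k_l", "k_g", "c0")


@dataclass(frozen=True)
class ATParams:
    """Parameters of the three-phase kinetic model.

    cmro2
        Metabolic production scale; enters the signal as ``2*alpha*cmro2``
        in concentration units per minute.
    k_l
        First-order loss (washout) rate in 1/min.
    k_g
        Gain coefficient for recirculated labelled body water.
    alpha
        ¹⁷O enrichment fraction of the inhaled gas (0.70 for the
        70%-enriched gas used in the inhalation experiments).
    c0
        Baseline H₂¹⁷O concentration in mmol/L, set by the 0.037% natural
        abundance of ¹⁷O in body water.
    t_a, t_b
        Start and end of gas inhalation, minutes.
    """

    cmro2: float
    k_l: float
    k_g: float
    alpha: float = 0.70
    c0: float = 11.7
    t_a: float = 10.0
    t_b: float = 21.0

    def __post_init__(self) -> None:
        if min(self.cmro2, self.k_l, self.k_g) < 0:
            raise ValueError("cmro2, k_l and k_g must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if not self.t_a < self.t_b:
            raise ValueError("t_a must precede t_b")

    def replace(self, **kwargs) -> "ATParams":
        return replace(self, **kwargs)


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit of the kinetic model."""

    params: ATParams
    adjusted_r2: float
    residual_norm: float
    converged: bool
    n_iter: int
    n_free: int = len(DEFAULT_FREE)
    message: str = ""


def _phase_responses(tau: np.ndarray, k_l: float) -> Tuple[np.ndarray, np.ndarray]:
    """Unit responses during inhalation, as functions of tau = t − t_a.

    f1 multiplies the production term P = 2*alpha*cmro2, f2 multiplies k_g:

        f1 = (1 − exp(−k·tau)) / k
        f2 = (k·tau − 1 + exp(−k·tau)) / k²

    For k·tau → 0 both suffer catastrophic cancellation, so small k_l uses
    the Taylor expansions f1 = tau·(1 − k·tau/2 + (k·tau)²/6 − …) and
    f2 = tau²·(1/2 − k·tau/6 + (k·tau)²/24 − …).
    """
    if k_l < K_SMALL:
        kt = k_l * tau
        f1 = tau * (1.0 - kt / 2.0 + kt**2 / 6.0 - kt**3 / 24.0)
        f2 = tau**2 * (0.5 - kt / 6.0 + kt**2 / 24.0 - kt**3 / 120.0)
        return f1, f2
    em = np.exp(-k_l * tau)
    f1 = (1.0 - em) / k_l
    f2 = (k_l * tau - 1.0 + em) / k_l**2
    return f1, f2


def at_forward(params: ATParams, times: Sequence[float]) -> SignalCurve:
    """Evaluate the closed-form solution C(t) of the kinetic model.

    Piecewise solution (y = C − c0, P = 2·alpha·cmro2, D = t_b − t_a):

    * baseline, t ≤ t_a:   y = 0
    * inhalation, tau = t − t_a in [0, D]:
          y = P·f1(tau) + k_g·f2(tau)          (responses above)
    * decay, tau = t − t_b ≥ 0:
          y = (y_b + k_g·D·tau)·exp(−k_l·tau)
      where y_b = y at t_b. The resonant ``tau·exp`` term is the exact
      response to the exponentially decaying recirculation excess X(t).

    C is continuous, equals c0 for all t ≤ t_a, and is non-decreasing on
    [t_a, t_b]. Returns a :class:`SignalCurve` with phase markers attached.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a non-empty 1D array")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    p = params
    prod = 2.0 * p.alpha * p.cmro2
    dur = p.t_b - p.t_a
    y = np.zeros_like(t)

    rising = (t > p.t_a) & (t <= p.t_b)
    if np.any(rising):
        f1, f2 = _phase_responses(t[rising] - p.t_a, p.k_l)
        y[rising] = prod * f1 + p.k_g * f2

    decaying = t > p.t_b
    if np.any(decaying):
        f1b, f2b = _phase_responses(np.array([dur]), p.k_l)
        y_b = float(prod * f1b[0] + p.k_g * f2b[0])
        tau = t[decaying] - p.t_b
        y[decaying] = (y_b + p.k_g * dur * tau) * np.exp(-p.k_l * tau)

    return SignalCurve(t, p.c0 + y, t_a=p.t_a, t_b=p.t_b, units="mmol/L")


def adjusted_r2(observed: Sequence[float], fitted: Sequence[float], n_params: int) -> float:
    """Adjusted coefficient of determination.

        R² = 1 − SS_res / SS_tot
        adjusted R² = 1 − (1 − R²)·(n − 1)/(n − n_params − 1)

    SS_tot is taken about the mean of the observed values. Requires
    ``n > n_params + 1`` and a non-constant observed vector.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.ndim != 1:
        raise ValueError("observed and fitted must be 1D arrays of equal length")
    n = obs.size
    if n <= n_params + 1:
        raise ValueError(f"need n > n_params + 1, got n={n}, n_params={n_params}")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; R² undefined")
    ss_res = float(np.sum((obs - fit) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _default_bounds(curve: SignalCurve, fixed: Dict[str, float]) -> Dict[str, Tuple[float, float]]:
    """Data-driven non-negativity bounds for the free parameters."""
    vals = curve.values
    t_a = fixed.get("t_a", curve.t_a)
    t_b = fixed.get("t_b", curve.t_b)
    alpha = fixed.get("alpha", 0.70)
    dur = max(t_b - t_a, 1e-6)
    baseline = vals[curve.times < t_a]
    c0_guess = float(baseline.mean()) if baseline.size else float(vals[0])
    rise = max(float(vals.max()) - c0_guess, 1e-6 * max(abs(c0_guess), 1.0))
    return {
        "cmro2": (0.0, 20.0 * rise / (2.0 * max(alpha, 0.05) * dur)),
        "k_l": (0.0, 2.0),
        "k_g": (0.0, 40.0 * rise / dur**2),
        "c0": (1e-9, 2.0 * float(vals.max()) + 1e-9),
    }


def at_fit(
    curve: SignalCurve,
    fixed: Optional[Dict[str, float]] = None,
    init: Optional[ATParams] = None,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    n_starts: int = 5,
    seed: int = 0,
    forward: Callable[[ATParams, np.ndarray], SignalCurve] = at_forward,
) -> FitResult:
    """Fit the kinetic model to a measured curve by nonlinear least squares.

    Parameters not named in ``fixed`` (default free set: cmro2, k_l, k_g,
    c0) are optimised with non-negativity bounds; ``alpha``, ``t_a`` and
    ``t_b`` default to 0.70 and the curve's phase markers. The loss is
    unweighted least squares. To escape local minima the optimiser is
    restarted from ``n_starts`` Halton points spread over the bounding box
    (deterministic given ``seed``); the best-residual solution is returned
    together with its adjusted R². The ``forward`` callable is pluggable so
    alternative functional forms of the three-phase model can be fitted
    with the same machinery.
    """
    fixed = dict(fixed or {})
    fixed.setdefault("alpha", 0.70)
    if curve.t_a is not None:
        fixed.setdefault("t_a", float(curve.t_a))
    if curve.t_b is not None:
        fixed.setdefault("t_b", float(curve.t_b))
    if "t_a" not in fixed or "t_b" not in fixed:
        raise ValueError("t_a and t_b must be fixed (from the curve markers or `fixed`)")

    free = [name for name in DEFAULT_FREE if name not in fixed]
    t, v = curve.times, curve.values
    for lo, hi, phase in ((-np.inf, fixed["t_a"], "baseline"),
                          (fixed["t_a"], fixed["t_b"], "inhalation"),
                          (fixed["t_b"], np.inf, "decay")):
        if np.count_nonzero((t > lo) & (t <= hi)) < 3:
            raise ValueError(f"curve must cover all three phases with >= 3 points each "
                             f"(too few in {phase})")

    if np.ptp(v) == 0 and "cmro2" in free:
        # a flat curve carries no information about the production rate
        params = _build_params({name: 0.0 for name in free} | {"c0": float(v[0])}, free, fixed)
        return FitResult(params, adjusted_r2=float("nan"), residual_norm=0.0,
                         converged=False, n_iter=0, n_free=len(free),
                         message="non-identifiable: constant curve with free cmro2")

    all_bounds = _default_bounds(curve, fixed)
    if bounds:
        all_bounds.update(bounds)
    lo = np.array([all_bounds[name][0] for name in free])
    hi = np.array([all_bounds[name][1] for name in free])

    def residuals(theta: np.ndarray) -> np.ndarray:
        params = _build_params(dict(zip(free, theta)), free, fixed)
        return forward(params, t).values - v

    starts = []
    if init is not None:
        starts.append(np.clip([getattr(init, name) for name in free], lo, hi))
    halton = qmc.Halton(d=len(free), scramble=True, seed=seed)
    starts.extend(qmc.scale(halton.random(max(n_starts - len(starts), 1)), lo, hi))

    best = None
    n_iter = 0
    for x0 in starts:
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - defensive; trf is robust here
            continue
        n_iter += int(sol.nfev)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:  # pragma: no cover
        raise RuntimeError("all optimisation starts failed")

    params = _build_params(dict(zip(free, best.x)), free, fixed)
    fitted = forward(params, t).values
    resid_norm = float(np.linalg.norm(fitted - v))
    try:
        adj = adjusted_r2(v, fitted, n_params=len(free))
    except ValueError:
        adj = float("nan")
    return FitResult(params, adjusted_r2=adj, residual_norm=resid_norm,
                     converged=bool(best.success), n_iter=n_iter, n_free=len(free),
                     message=str(best.message))


def _build_params(free_values: Dict[str, float], free: Iterable[str],
                  fixed: Dict[str, float]) -> ATParams:
    kwargs = {**{k: float(v) for k, v in fixed.items()},
              **{k: float(free_values[k]) for k in free}}
    kwargs.setdefault("cmro2", 0.0)
    kwargs.setdefault("k_l", 0.0)
    kwargs.setdefault("k_g", 0.0)
    return ATParams(**kwargs)
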