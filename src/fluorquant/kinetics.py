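"""Bi-exponential fluoride-leaching kinetics.

Fluoride release from borosilicate glass into buffer is described by

    c(t) = A · (1 − B·exp(−k1·t) − C·exp(−k2·t))

with plateau concentration ``A``, dimensionless amplitudes ``B`` and ``C``,
and rate constants ``k1 >= k2 > 0`` (per hour). Two rate processes capture
the steep initial rise and the slow approach to plateau seen in glass-tube
time courses. Fitting is multi-start nonlinear least squares because the
objective is multimodal in (k1, k2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "LeachingModel",
    "TimeCourseSample",
    "KineticsFit",
    "evaluate_model",
    "fit_leaching",
    "compare_conditions",
    "time_to_fraction",
]


@dataclass(frozen=True)
class LeachingModel:
    """Parameters of the bi-exponential leaching curve.

    ``A``: plateau concentration (μM or normalised units), > 0.
    ``B``, ``C``: dimensionless amplitudes of the fast and slow phases.
    ``k1``, ``k2``: rates in 1/h, canonically ordered ``k1 >= k2 > 0``.
    """

    A: float
    B: float
    C: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("plateau A must be > 0")
        if self.k2 <= 0 or self.k1 <= 0:
            raise ValueError("rates must be > 0")
        if self.k1 < self.k2:
            raise ValueError("canonical ordering requires k1 >= k2")
        if not (math.isfinite(self.B) and math.isfinite(self.C)):
            raise ValueError("amplitudes must be finite")

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return evaluate_model(self, t)

    @property
    def initial_rate(self) -> float:
        """dc/dt at t = 0: A·(B·k1 + C·k2)."""
        return self.A * (self.B * self.k1 + self.C * self.k2)


@dataclass(frozen=True)
class TimeCourseSample:
    """One observation of a leaching time course: hours and μM."""

    time: float
    concentration: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class KineticsFit:
    """Result of a multi-start bi-exponential fit."""

    model: LeachingModel
    standard_errors: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    n_starts_used: int
    degenerate_rates: bool = False
    mono_fit: "MonoFit | None" = None

    @property
    def prefers_mono(self) -> bool:
        """True when a mono-exponential explains the data essentially as well.

        Uses an F-test between the nested models at the 5% level; only
        meaningful when a mono comparison fit is attached.
        """
        if self.mono_fit is None:
            return False
        from scipy.stats import f as f_dist

        df_full = self.n_points - 5
        if df_full <= 0 or self.rss <= 0:
            return False
        fstat = ((self.mono_fit.rss - self.rss) / 2.0) / (self.rss / df_full)
        p = f_dist.sf(max(fstat, 0.0), 2, df_full)
        return p > 0.05


@dataclass
class MonoFit:
    """Mono-exponential comparison fit c(t) = A·(1 − B·exp(−k·t))."""

    A: float
    B: float
    k: float
    rss: float


def evaluate_model(model: LeachingModel, t: float | np.ndarray):
    """Evaluate the leaching curve at time(s) ``t`` (hours, >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    val = model.A * (
        1.0 - model.B * np.exp(-model.k1 * t_arr) - model.C * np.exp(-model.k2 * t_arr)
    )
    return float(val) if np.isscalar(t) or t_arr.ndim == 0 else val


def _biexp(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, c, k1, k2 = params
    return a * (1.0 - b * np.exp(-k1 * t) - c * np.exp(-k2 * t))


def _linear_amplitudes(t, y, a, k1, k2):
    """Solve B, C by linear least squares at fixed plateau and rates."""
    # y = a - a·B·e^{-k1 t} - a·C·e^{-k2 t}
    design = np.column_stack([-a * np.exp(-k1 * t), -a * np.exp(-k2 * t)])
    coef, *_ = np.linalg.lstsq(design, y - a, rcond=None)
    return coef


def fit_leaching(
    samples: list[TimeCourseSample] | np.ndarray,
    n_starts: int = 20,
    seed: int | None = None,
    constrain_origin: bool = False,
) -> KineticsFit:
    """Fit the bi-exponential leaching model by multi-start least squares.

    Starting points: plateau from the late-time mean; rate pairs log-spaced
    over [1/t_max, 10/t_min]; amplitudes from a linear solve at fixed rates.
    The best-RSS solution is returned with ``k1 >= k2`` enforced by
    relabelling. ``constrain_origin`` imposes B + C = 1 (zero concentration
    at t = 0).

    Parameters standard errors come from the Jacobian at the optimum. Rates
    closer than a factor 1.2 are flagged degenerate and a mono-exponential
    comparison fit is attached.
    """
    if isinstance(samples, np.ndarray):
        t = np.asarray(samples[:, 0], dtype=float)
        y = np.asarray(samples[:, 1], dtype=float)
    else:
        t = np.array([s.time for s in samples], dtype=float)
        y = np.array([s.concentration for s in samples], dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 time points")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    rng = np.random.default_rng(seed)
    t_max = float(t.max())
    t_min = float(t[t > 0].min()) if np.any(t > 0) else 1.0
    a0 = float(np.mean(y[t >= 0.75 * t_max])) or float(np.max(y)) or 1.0
    k_lo, k_hi = 1.0 / t_max, 10.0 / t_min
    k_grid = np.geomspace(k_lo, k_hi, max(4, int(np.ceil(np.sqrt(2 * n_starts)))))

    def residuals(p):
        if constrain_origin:
            a, b, k1, k2 = p
            c = 1.0 - b
        else:
            a, b, c, k1, k2 = p
        return a * (1.0 - b * np.exp(-k1 * t) - c * np.exp(-k2 * t)) - y

    # rate pairs: deterministic grid pairs first, then random log-uniform pairs
    pairs = [(kf, ks) for kf in k_grid for ks in k_grid if kf > ks]
    rng.shuffle(pairs)
    while len(pairs) < n_starts:
        kf, ks = np.exp(rng.uniform(np.log(k_lo), np.log(k_hi), size=2))
        pairs.append((max(kf, ks), min(kf, ks)))

    best = None
    n_used = 0
    for kf, ks in pairs[:n_starts]:
        n_used += 1
        b0, c0 = _linear_amplitudes(t, y, a0, kf, ks)
        if constrain_origin:
            x0 = np.array([a0, b0, kf, ks])
            lb = [1e-12, -np.inf, 1e-9, 1e-9]
            ub = [np.inf, np.inf, np.inf, np.inf]
        else:
            x0 = np.array([a0, b0, c0, kf, ks])
            lb = [1e-12, -np.inf, -np.inf, 1e-9, 1e-9]
            ub = [np.inf] * 5
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)

    if best is None:
        raise RuntimeError("bi-exponential fit failed from all starting points")

    rss, sol = best
    if constrain_origin:
        a, b, k1, k2 = sol.x
        c = 1.0 - b
    else:
        a, b, c, k1, k2 = sol.x
    # canonical ordering by relabelling the two phases
    if k1 < k2:
        k1, k2, b, c = k2, k1, c, b

    # standard errors from J^T J at the optimum (full 5-parameter Jacobian)
    se = _standard_errors(t, y, np.array([a, b, c, k1, k2]), rss)

    degenerate = bool((k1 / max(k2, 1e-300)) < 1.2)
    model = LeachingModel(A=float(a), B=float(b), C=float(c), k1=float(k1), k2=float(k2))
    fit = KineticsFit(
        model=model,
        standard_errors=se,
        rss=rss,
        n_points=len(t),
        converged=True,
        n_starts_used=n_used,
        degenerate_rates=degenerate,
    )
    # mono-exponential comparison fit: always attached so the nested-model
    # F-test can flag over-parameterised fits, not only degenerate-rate ones
    fit.mono_fit = _fit_mono(t, y, a, max(k1, 1e-6))
    return fit


def _standard_errors(t, y, params, rss) -> dict[str, float]:
    a, b, c, k1, k2 = params
    e1, e2 = np.exp(-k1 * t), np.exp(-k2 * t)
    jac = np.column_stack(
        [1.0 - b * e1 - c * e2, -a * e1, -a * e2, a * b * t * e1, a * c * t * e2]
    )
    dof = max(len(t) - 5, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        diag = np.clip(np.diag(cov), 0.0, None)
        ses = np.sqrt(diag)
    except np.linalg.LinAlgError:
        ses = np.full(5, np.nan)
    return dict(zip(["A", "B", "C", "k1", "k2"], map(float, ses)))


def _fit_mono(t, y, a0, k0) -> MonoFit:
    def resid(p):
        a, b, k = p
        return a * (1.0 - b * np.exp(-k * t)) - y

    sol = least_squares(
        resid, np.array([a0, 1.0, k0]), bounds=([1e-12, -np.inf, 1e-9], [np.inf] * 3)
    )
    return MonoFit(*map(float, sol.x), rss=float(2.0 * sol.cost))


def time_to_fraction(model: LeachingModel, fraction: float = 0.9) -> float:
    """Time (hours) at which the curve first reaches ``fraction``·A."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    target = fraction * model.A

    def f(t):
        return evaluate_model(model, t) - target

    hi = 1.0 / model.k2
    while f(hi) < 0 and hi < 1e9 / model.k2:
        hi *= 2.0
    if f(0.0) >= 0:
        return 0.0
    return float(brentq(f, 0.0, hi))


def compare_conditions(fit_a: KineticsFit, fit_b: KineticsFit) -> dict:
    """Compare two leaching fits (e.g. 25 °C vs 60 °C incubation).

    Reports the plateau ratio, the ratio of effective initial rates
    A·(B·k1 + C·k2), and each condition's time to reach 90% of plateau.
    """
    for name, fit in (("a", fit_a), ("b", fit_b)):
        if not fit.converged:
            raise ValueError(f"fit {name} did not converge")
    t90_a = time_to_fraction(fit_a.model, 0.9)
    t90_b = time_to_fraction(fit_b.model, 0.9)
    return {
        "plateau_a": fit_a.model.A,
        "plateau_b": fit_b.model.A,
        "plateau_ratio_b_over_a": fit_b.model.A / fit_a.model.A,
        "initial_rate_a": fit_a.model.initial_rate,
        "initial_rate_b": fit_b.model.initial_rate,
        "initial_rate_ratio_b_over_a": fit_b.model.initial_rate
        / fit_a.model.initial_rate,
        "time_to_90pct_a_h": t90_a,
        "time_to_90pct_b_h": t90_b,
        "time_to_90pct_ratio_b_over_a": t90_b / t90_a if t90_a > 0 else float("inf"),
    }
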