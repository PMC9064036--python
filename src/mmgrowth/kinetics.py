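"""Concentration-dependent growth-rate models and replicate-level fitting.

Growth of *C. glutamicum* on protocatechuic acid (PCA) rises with
concentration, peaks in the low-millimolar range, and collapses at high
concentration (bacteriostasis).  Two models capture this:

* single-step: a Monod term times a Hill-type inhibition factor,
  ``mu(c) = mu_max * c/(K + c) * 1/(1 + (c/K_I)^n_I)``
* two-step: two Michaelis-Menten terms in parallel (two uptake routes /
  pathways), both multiplied by the same inhibition factor.

Plain Monod and Teissier kinetics are kept as comparators.  Fitting is
unweighted least squares on replicate-level (concentration, mu) pairs —
individual replicate results, not per-concentration means — with a
deterministic multi-start grid so results are reproducible without a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SingleStepParams",
    "TwoStepParams",
    "GrowthObservation",
    "FitResult",
    "TABLE_SINGLE",
    "TABLE_TWO",
    "TABLE_MONOD",
    "TABLE_TEISSIER",
    "inhibition",
    "mu_single",
    "mu_two",
    "mu_monod",
    "mu_teissier",
    "fit_kinetics",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class SingleStepParams:
    """Monod x Hill-inhibition parameters.

    mu_max in 1/h, K (half-velocity) and K_I (inhibition constant) in
    mmol/L, n_I the dimensionless Hill steepness.
    """

    mu_max: float
    K: float
    K_I: float
    n_I: float

    def __post_init__(self) -> None:
        _require_positive(mu_max=self.mu_max, K=self.K, K_I=self.K_I, n_I=self.n_I)


@dataclass(frozen=True)
class TwoStepParams:
    """Dual Michaelis-Menten x Hill-inhibition parameters; K1 <= K2 by convention."""

    mu1: float
    mu2: float
    K1: float
    K2: float
    K_I: float
    n_I: float

    def __post_init__(self) -> None:
        _require_positive(
            mu1=self.mu1, mu2=self.mu2, K1=self.K1, K2=self.K2,
            K_I=self.K_I, n_I=self.n_I,
        )


@dataclass(frozen=True)
class GrowthObservation:
    """One replicate's population growth rate at one concentration."""

    concentration: float  # mmol/L
    mu: float  # 1/h, 0 allowed (non-growing replicate)
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")


#: Published fits for growth of C. glutamicum on PCA (this device) and the
#: prior monolayer-chamber study's comparators.
TABLE_SINGLE = SingleStepParams(mu_max=0.37, K=0.185, K_I=23.37, n_I=4.2)
TABLE_TWO = TwoStepParams(mu1=0.22, mu2=0.2, K1=0.061, K2=1.71, K_I=21.66, n_I=3.5)
TABLE_MONOD = (0.26, 0.020)
TABLE_TEISSIER = (0.20, 0.014)


def inhibition(c, K_I: float, n_I: float):
    """Hill-type inhibition factor ``1 / (1 + (c/K_I)^n_I)`` in (0, 1].

    Equals 1/2 at c = K_I; -> 1 as c -> 0 and -> 0 as c -> infinity.  For
    c > K_I the algebraically identical form K_I^n / (K_I^n + c^n) is
    evaluated in the log domain to avoid overflow at large c or n.
    """
    _require_positive(K_I=K_I, n_I=n_I)
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(over="ignore"):
        ratio = np.where(c > 0, c / K_I, 0.0)
        out = 1.0 / (1.0 + np.exp(n_I * np.log(np.where(ratio > 0, ratio, 1.0))))
        out = np.where(ratio > 0, out, 1.0)
    return out if out.ndim else float(out)


def mu_monod(c, mu_max: float, K: float):
    """Plain Monod kinetic ``mu_max * c / (K + c)``."""
    _require_positive(mu_max=mu_max, K=K)
    c = np.asarray(c, dtype=float)
    out = mu_max * c / (K + c)
    return out if out.ndim else float(out)


def mu_teissier(c, mu_max: float, K: float):
    """Teissier kinetic ``mu_max * (1 - exp(-c/K))``."""
    _require_positive(mu_max=mu_max, K=K)
    c = np.asarray(c, dtype=float)
    out = mu_max * (1.0 - np.exp(-c / K))
    return out if out.ndim else float(out)


def mu_single(c, params: SingleStepParams):
    """Single-step kinetic: Monod saturation times Hill inhibition; mu(0) = 0."""
    c_arr = np.asarray(c, dtype=float)
    out = (
        params.mu_max
        * c_arr
        / (params.K + c_arr)
        * inhibition(c_arr, params.K_I, params.n_I)
    )
    return out if out.ndim else float(out)


def mu_two(c, params: TwoStepParams):
    """Two-step kinetic: parallel Michaelis-Menten terms times Hill inhibition."""
    c_arr = np.asarray(c, dtype=float)
    mm = params.mu1 * c_arr / (params.K1 + c_arr) + params.mu2 * c_arr / (
        params.K2 + c_arr
    )
    out = mm * inhibition(c_arr, params.K_I, params.n_I)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting

# parameter names, physically plausible bounds, and model functions keyed by
# model name; bounds reflect the magnitudes of the published fits
_RATE_BOUNDS = (1e-6, 2.0)
_K_BOUNDS = (1e-4, 10.0)
_KI_BOUNDS = (1.0, 1e3)
_NI_BOUNDS = (0.5, 10.0)

_MODELS: dict[str, dict] = {
    "single": {
        "names": ("mu_max", "K", "K_I", "n_I"),
        "bounds": (_RATE_BOUNDS, _K_BOUNDS, _KI_BOUNDS, _NI_BOUNDS),
        "fn": lambda c, th: mu_single(c, SingleStepParams(*th)),
        "starts_per_param": 3,
    },
    "two": {
        "names": ("mu1", "mu2", "K1", "K2", "K_I", "n_I"),
        "bounds": (_RATE_BOUNDS, _RATE_BOUNDS, _K_BOUNDS, _K_BOUNDS,
                   _KI_BOUNDS, _NI_BOUNDS),
        "fn": lambda c, th: mu_two(c, TwoStepParams(*th)),
        "starts_per_param": 2,
    },
    "monod": {
        "names": ("mu_max", "K"),
        "bounds": (_RATE_BOUNDS, _K_BOUNDS),
        "fn": lambda c, th: mu_monod(c, *th),
        "starts_per_param": 3,
    },
    "teissier": {
        "names": ("mu_max", "K"),
        "bounds": (_RATE_BOUNDS, _K_BOUNDS),
        "fn": lambda c, th: mu_teissier(c, *th),
        "starts_per_param": 3,
    },
}


@dataclass
class FitResult:
    """Outcome of a multi-start least-squares kinetic fit."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    n_obs: int
    n_starts: int
    converged: bool
    start_grid: list[tuple[float, ...]] = field(default_factory=list, repr=False)
    warnings: list[str] = field(default_factory=list)

    def predict(self, c):
        theta = tuple(self.params[name] for name in _MODELS[self.model]["names"])
        return _MODELS[self.model]["fn"](np.asarray(c, dtype=float), theta)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "stderr": self.stderr,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "warnings": self.warnings,
            "start_grid": [list(s) for s in self.start_grid],
        }


def _start_grid(bounds: tuple, per_param: int) -> list[tuple[float, ...]]:
    """Deterministic multi-start grid: geometric interior points of each bound."""
    axes = []
    for lo, hi in bounds:
        pts = np.geomspace(lo, hi, per_param + 2)[1:-1]
        axes.append(pts)
    return [tuple(p) for p in itertools.product(*axes)]


def fit_kinetics(
    observations: list[GrowthObservation],
    model: str = "single",
    max_starts: int | None = None,
) -> FitResult:
    """Fit a kinetic model to replicate-level growth rates by least squares.

    All individual replicate results are used (zero-growth replicates enter
    as mu = 0), not per-concentration means.  A deterministic grid of initial
    guesses is tried and the best final residual wins, so identical inputs
    always give identical fits.  Standard errors come from the Gauss-Newton
    curvature at the optimum, ``cov = (J'J)^-1 * rss / (n - p)``.

    Raises
    ------
    ValueError
        If the model name is unknown, or the data are under-determined
        (fewer than p + 1 observations or fewer than 3 distinct
        concentrations).
    RuntimeError
        If no start converges; the per-start outcomes are included.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    spec = _MODELS[model]
    names = spec["names"]
    bounds = spec["bounds"]
    p = len(names)

    c = np.array([o.concentration for o in observations], dtype=float)
    y = np.array([o.mu for o in observations], dtype=float)
    n = c.size
    n_distinct = np.unique(c).size
    if n < p + 1 or n_distinct < 3:
        raise ValueError(
            f"under-determined fit: model {model!r} has {p} parameters and "
            f"needs at least {p + 1} observations over >= 3 distinct "
            f"concentrations; got {n} observations at {n_distinct} concentration(s)"
        )

    fn = spec["fn"]
    starts = _start_grid(bounds, spec["starts_per_param"])
    if max_starts is not None:
        starts = starts[:max_starts]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return fn(c, tuple(theta)) - y

    best = None
    failures = []
    for theta0 in starts:
        try:
            sol = least_squares(
                residuals, x0=np.array(theta0), bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as err:  # pragma: no cover - solver-internal failure
            failures.append((theta0, repr(err)))
            continue
        if not sol.success:
            failures.append((theta0, sol.message))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        lines = "\n".join(f"  start {s}: {msg}" for s, msg in failures)
        raise RuntimeError(f"no start converged for model {model!r}:\n{lines}")

    theta = best.x
    rss = float(2.0 * best.cost)
    warns: list[str] = []

    # identifiability ordering for the two parallel kinetics
    if model == "two":
        i_k1, i_k2 = names.index("K1"), names.index("K2")
        i_m1, i_m2 = names.index("mu1"), names.index("mu2")
        if theta[i_k1] > theta[i_k2]:
            theta[[i_k1, i_k2]] = theta[[i_k2, i_k1]]
            theta[[i_m1, i_m2]] = theta[[i_m2, i_m1]]
        for i in (i_m1, i_m2):
            if np.isclose(theta[i], lo[i]) or np.isclose(theta[i], hi[i]):
                warns.append(f"{names[i]} at bound {theta[i]:g}")

    for i, name in enumerate(names):
        if np.isclose(theta[i], hi[i], rtol=1e-3):
            warns.append(f"{name} at upper bound {hi[i]:g}")

    # standard errors from local curvature; guard the dof == 0 edge
    J = best.jac
    dof = max(n - p, 1)
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        warns.append("singular curvature; standard errors unavailable")

    return FitResult(
        model=model,
        params={name: float(v) for name, v in zip(names, theta)},
        stderr={name: float(v) for name, v in zip(names, se)},
        rss=rss,
        n_obs=n,
        n_starts=len(starts),
        converged=True,
        start_grid=starts,
        warnings=warns,
    )
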