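"""Degree-distribution model selection via maximum likelihood and KS distance.

Four candidate families are fitted to the giant component's degree sequence
as *discrete* distributions on k in {k_min, k_min+1, ...} (degrees are
integers; k_min defaults to 1 so the whole observed range is modelled, with
no lower-cutoff optimization):

    exponential          P(k) ∝ exp(-λk)
    power law            P(k) ∝ k^(-α)          (α > 1)
    truncated power law  P(k) ∝ k^(-α) exp(-λk)
    log-normal           P(k) ∝ (1/k) exp(-(ln k - μ)² / (2σ²))

Normalizing constants are computed by direct summation over the support up
to a truncation bound of max(10 · max observed degree, 10^5); with every
family's tail decaying at least exponentially fast past the data (or
power-law with α > 1), the remainder beyond that bound is negligible
relative to the 1e-9 normalization tolerance asserted in the tests.

Families are ranked by the Kolmogorov–Smirnov distance between the fitted
CDF and the empirical CDF, evaluated at the observed degrees. Because the
truncated power law nests both the pure power law (λ → 0) and the
exponential (α → 0), KS distances of nested fits can coincide up to
optimizer noise; ranking therefore treats KS values within a small band
(2e-3) as tied and prefers the family with fewer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.optimize

from .descriptives import giant_component

__all__ = [
    "FitResult", "FAMILIES", "degree_sequence", "family_pmf", "sample_family",
    "fit_family", "ks_distance", "rank_fits", "DegenerateSampleError",
]

FAMILIES = ("lognormal", "exponential", "powerlaw", "truncated_powerlaw")
_N_PARAMS = {"exponential": 1, "powerlaw": 1, "truncated_powerlaw": 2, "lognormal": 2}

KS_TIE_TOL = 2e-3


class DegenerateSampleError(ValueError):
    """The degree sample cannot identify the family (e.g. all values equal)."""


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family to a degree sample."""

    family: str
    params: dict[str, float]
    loglik: float
    ks_distance: float = field(default=np.nan)
    k_min: int = 1
    n: int = 0

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]


def degree_sequence(network: nx.Graph, scope: str = "giant") -> np.ndarray:
    """Degree multiset of the giant component (or whole network)."""
    g = giant_component(network) if scope == "giant" else network
    return np.array(sorted((d for _, d in g.degree()), reverse=True), dtype=int)


def _support(k_min: int, k_max_obs: int) -> np.ndarray:
    bound = max(10 * k_max_obs, 100_000)
    return np.arange(k_min, bound + 1)


def _log_weights(family: str, k: np.ndarray, params: dict[str, float]) -> np.ndarray:
    logk = np.log(k)
    if family == "exponential":
        return -params["lam"] * k
    if family == "powerlaw":
        return -params["alpha"] * logk
    if family == "truncated_powerlaw":
        return -params["alpha"] * logk - params["lam"] * k
    if family == "lognormal":
        mu, sigma = params["mu"], params["sigma"]
        return -logk - (logk - mu) ** 2 / (2 * sigma**2)
    raise ValueError(f"unknown family {family!r}")


def family_pmf(family: str, params: dict[str, float], k_min: int = 1,
               k_max_obs: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """(support, pmf) of a fitted family, normalized over the truncated support."""
    k = _support(k_min, k_max_obs)
    logw = _log_weights(family, k, params)
    logw -= logw.max()
    w = np.exp(logw)
    return k, w / w.sum()


def sample_family(family: str, params: dict[str, float], n: int, seed: int,
                  k_min: int = 1, k_max: int = 10_000) -> np.ndarray:
    """Draw n values from a discrete family — the tests' sampling oracle."""
    rng = np.random.default_rng(seed)
    k = np.arange(k_min, k_max + 1)
    logw = _log_weights(family, k, params)
    logw -= logw.max()
    w = np.exp(logw)
    return rng.choice(k, size=n, p=w / w.sum())


def _neg_loglik(family: str, theta: np.ndarray, stats: dict, k: np.ndarray) -> float:
    if family == "exponential":
        params = {"lam": theta[0]}
    elif family == "powerlaw":
        params = {"alpha": theta[0]}
    elif family == "truncated_powerlaw":
        params = {"alpha": theta[0], "lam": theta[1]}
    else:
        params = {"mu": theta[0], "sigma": theta[1]}
    logw = _log_weights(family, k, params)
    mx = logw.max()
    logz = mx + np.log(np.exp(logw - mx).sum())
    n = stats["n"]
    if family == "exponential":
        ll = -params["lam"] * stats["sum_k"]
    elif family == "powerlaw":
        ll = -params["alpha"] * stats["sum_logk"]
    elif family == "truncated_powerlaw":
        ll = -params["alpha"] * stats["sum_logk"] - params["lam"] * stats["sum_k"]
    else:
        mu, sigma = params["mu"], params["sigma"]
        ll = -stats["sum_logk"] - (
            stats["sum_logk2"] - 2 * mu * stats["sum_logk"] + n * mu**2
        ) / (2 * sigma**2)
    return -(ll - n * logz)


_BOUNDS = {
    "exponential": [(1e-6, 20.0)],
    "powerlaw": [(1.0 + 1e-6, 20.0)],
    "truncated_powerlaw": [(1e-9, 20.0), (1e-9, 20.0)],
    "lognormal": [(-10.0, 15.0), (1e-3, 10.0)],
}


def _initial_guess(family: str, degrees: np.ndarray) -> np.ndarray:
    logs = np.log(degrees)
    if family == "exponential":
        mean = degrees.mean()
        return np.array([1.0 / max(mean - degrees.min() + 0.5, 0.1)])
    if family == "powerlaw":
        # Hill-style continuous estimate, clipped into bounds
        alpha = 1.0 + len(degrees) / np.sum(np.log(degrees / (degrees.min() - 0.5)))
        return np.array([float(np.clip(alpha, 1.01, 19.0))])
    if family == "truncated_powerlaw":
        return np.array([1.0, 1.0 / max(degrees.mean(), 1.0)])
    return np.array([float(logs.mean()), float(max(logs.std(), 0.05))])


def fit_family(degrees, family: str, k_min: int = 1) -> FitResult:
    """Maximum-likelihood fit of one discrete family to a degree sample."""
    degrees = np.asarray(degrees, dtype=int)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if len(degrees) < 10:
        raise ValueError("need at least 10 observations")
    if degrees.min() < k_min:
        raise ValueError(f"observations below k_min={k_min}")
    if np.all(degrees == degrees[0]):
        raise DegenerateSampleError("all degrees equal; family fit is degenerate")

    k = _support(k_min, int(degrees.max()))
    logs = np.log(degrees)
    stats = {
        "n": len(degrees),
        "sum_k": float(degrees.sum()),
        "sum_logk": float(logs.sum()),
        "sum_logk2": float((logs**2).sum()),
    }
    x0 = _initial_guess(family, degrees)
    bounds = _BOUNDS[family]
    if len(bounds) == 1:
        res = scipy.optimize.minimize_scalar(
            lambda t: _neg_loglik(family, np.array([t]), stats, k),
            bounds=bounds[0], method="bounded",
            options={"xatol": 1e-10},
        )
        theta = np.array([res.x])
        ok = res.success
    else:
        res = scipy.optimize.minimize(
            lambda t: _neg_loglik(family, t, stats, k),
            x0=x0, bounds=bounds, method="L-BFGS-B",
        )
        theta = res.x
        ok = res.success
    if not ok:
        raise RuntimeError(f"{family} fit did not converge: {res}")

    if family == "exponential":
        params = {"lam": float(theta[0])}
    elif family == "powerlaw":
        params = {"alpha": float(theta[0])}
    elif family == "truncated_powerlaw":
        params = {"alpha": float(theta[0]), "lam": float(theta[1])}
    else:
        params = {"mu": float(theta[0]), "sigma": float(theta[1])}

    fit = FitResult(
        family=family, params=params,
        loglik=-_neg_loglik(family, theta, stats, k),
        k_min=k_min, n=len(degrees),
    )
    return FitResult(**{**fit.__dict__, "ks_distance": ks_distance(degrees, fit)})


def ks_distance(degrees, fit: FitResult) -> float:
    """Max |empirical CDF - fitted CDF| over the observed degrees."""
    degrees = np.asarray(degrees, dtype=int)
    k, pmf = family_pmf(fit.family, fit.params, fit.k_min, int(degrees.max()))
    cdf = np.cumsum(pmf)
    uniq, counts = np.unique(degrees, return_counts=True)
    ecdf = np.cumsum(counts) / len(degrees)
    model = cdf[uniq - fit.k_min]
    return float(np.abs(ecdf - model).max())


def rank_fits(degrees, families=FAMILIES, k_min: int = 1,
              tie_tol: float = KS_TIE_TOL) -> tuple[list[FitResult], dict[str, Exception]]:
    """Fit all families and rank ascending by KS distance.

    KS values within ``tie_tol`` of the best of their group are treated as
    tied and ordered by parameter count (parsimony), which resolves the
    nesting degeneracies described in the module docstring. Per-family fit
    errors are collected, not propagated, unless every family fails.
    """
    fits: list[FitResult] = []
    errors: dict[str, Exception] = {}
    for family in families:
        try:
            fits.append(fit_family(degrees, family, k_min=k_min))
        except Exception as exc:  # noqa: BLE001 - per-family isolation is the contract
            errors[family] = exc
    if not fits:
        raise DegenerateSampleError(f"all families failed: {errors}")
    fits.sort(key=lambda f: f.ks_distance)
    ranked: list[FitResult] = []
    i = 0
    while i < len(fits):
        j = i
        while j + 1 < len(fits) and fits[j + 1].ks_distance - fits[i].ks_distance <= tie_tol:
            j += 1
        group = sorted(fits[i : j + 1], key=lambda f: (f.n_params, f.ks_distance))
        ranked.extend(group)
        i = j + 1
    return ranked, errors
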