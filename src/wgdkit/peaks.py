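"""Ks density smoothing and Gaussian multi-peak decomposition.

The density of a Ks sample is estimated with a Gaussian kernel of fixed
width (default 0.05) on a uniform grid, and the curve — not the raw sample —
is decomposed into a sum of Gaussian components by nonlinear least squares,
mirroring the MATLAB ksdensity + cftool procedure this emulates.

Component-number selection keeps the classical R² ≥ 0.95 floor but adds a
decisive-improvement rule: starting from one component, another component is
accepted only while it reduces the residual sum of squares by at least a
factor of 20.  A pair of strongly overlapping peaks (e.g. two
tetraploidizations close in time) leaves a single Gaussian with R² ≈ 0.97
yet is split by a second component at R² > 0.9999 — a >100-fold residual
drop — while for a genuinely single-peaked curve a second component buys
well under a 10-fold drop.  A plain "smallest k with R² ≥ 0.95" stop would
merge exactly the peak pairs this analysis exists to separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

DEFAULT_BANDWIDTH = 0.05
DEFAULT_WINDOW = (0.0, 3.0)
DEFAULT_GRID_POINTS = 601
R2_THRESHOLD = 0.95
MAX_COMPONENTS = 6
MIN_SAMPLE = 50
IMPROVEMENT_FACTOR = 20.0   # residual-SS drop required to accept another component
R2_SATURATED = 0.9999


class InsufficientDataError(ValueError):
    pass


class FitFailureError(RuntimeError):
    def __init__(self, message: str, best_fit: Optional["MixtureFit"] = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_in_window: int = 0
    n_total: int = 0

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class GaussianComponent:
    weight: float
    mean: float
    sd: float


@dataclass
class MixtureFit:
    components: list
    r2: float
    n_components: int = 0

    def __post_init__(self) -> None:
        self.components.sort(key=lambda c: c.mean)
        self.n_components = len(self.components)

    @property
    def principal(self) -> GaussianComponent:
        return max(self.components, key=lambda c: c.weight)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _gaussian_sum(x, *_flatten(self.components))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"component": i, "weight": c.weight, "mean": c.mean, "sd": c.sd,
              "r2": self.r2} for i, c in enumerate(self.components)])


def _flatten(components) -> list[float]:
    out: list[float] = []
    for c in components:
        out.extend((c.weight, c.mean, c.sd))
    return out


def _gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x, dtype=float)
    for i in range(len(params) // 3):
        w, m, s = params[3 * i : 3 * i + 3]
        y += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2.0 * np.pi))
    return y


def kde_density(sample: Sequence[float], bandwidth: float = DEFAULT_BANDWIDTH,
                window: tuple = DEFAULT_WINDOW, grid_points: int = DEFAULT_GRID_POINTS,
                min_sample: int = MIN_SAMPLE) -> DensityCurve:
    """Gaussian-kernel density of the in-window Ks values on a uniform grid.

    The curve is scaled by the in-window mass fraction, so its integral over
    the window tracks the fraction of the full sample inside the window.
    """
    values = np.asarray(sample, dtype=float)
    values = values[np.isfinite(values)]
    n_total = len(values)
    inside = values[(values >= window[0]) & (values <= window[1])]
    if len(inside) < min_sample:
        raise InsufficientDataError(
            f"only {len(inside)} Ks values inside window {window}; need {min_sample}")
    grid = np.linspace(window[0], window[1], grid_points)
    sd = np.std(inside, ddof=1)
    if sd == 0:
        dens = np.exp(-0.5 * ((grid - inside[0]) / bandwidth) ** 2)
        dens /= bandwidth * np.sqrt(2 * np.pi)
    else:
        kde = gaussian_kde(inside, bw_method=bandwidth / sd)
        dens = kde(grid)
    dens = dens * (len(inside) / n_total)
    return DensityCurve(grid=grid, density=dens, bandwidth=bandwidth,
                        n_in_window=len(inside), n_total=n_total)


def _initial_params(curve: DensityCurve, k: int) -> list[float]:
    dens = curve.density
    grid = curve.grid
    pk, _props = find_peaks(dens, prominence=0.005 * dens.max())
    order = np.argsort(dens[pk])[::-1]
    means = list(grid[pk][order][:k])
    support = grid[dens > 0.01 * dens.max()]
    if len(support) == 0:
        support = grid
    j = 0
    while len(means) < k:  # deterministic fallback inits inside the support
        means.append(float(np.quantile(support, (j + 0.5) / k)))
        j += 1
    means = sorted(means)
    total_mass = max(np.trapezoid(dens, grid), 1e-12)
    params: list[float] = []
    for m in means:
        params.extend((total_mass / k, m, 3.0 * curve.bandwidth))
    return params


def _split_inits(warm: "MixtureFit", curve: DensityCurve) -> list[list[float]]:
    """Initializations for a (k+1)-component fit from a k-component fit:
    one candidate per warm component, splitting that component into two."""
    inits = []
    for i, broad in enumerate(warm.components):
        rest = [c for j, c in enumerate(warm.components) if j != i]
        halves = [GaussianComponent(broad.weight / 2, broad.mean - 0.6 * broad.sd,
                                    max(broad.sd / np.sqrt(2), curve.bandwidth / 2)),
                  GaussianComponent(broad.weight / 2, broad.mean + 0.6 * broad.sd,
                                    max(broad.sd / np.sqrt(2), curve.bandwidth / 2))]
        inits.append(_flatten(rest + halves))
    return inits


def _fit_once(curve: DensityCurve, p0: list[float]) -> Optional[MixtureFit]:
    grid, dens = curve.grid, curve.density
    k = len(p0) // 3
    lb = [0.0, grid[0], curve.bandwidth / 2.0] * k
    ub = [np.inf, grid[-1], (grid[-1] - grid[0])] * k
    p0 = [min(max(p, l), u) for p, l, u in zip(p0, lb, ub)]
    try:
        popt, _ = curve_fit(_gaussian_sum, grid, dens, p0=p0, bounds=(lb, ub), maxfev=50000)
    except Exception:
        return None
    resid = dens - _gaussian_sum(grid, *popt)
    sst = np.sum((dens - dens.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
    comps = [GaussianComponent(float(popt[3 * i]), float(popt[3 * i + 1]), float(popt[3 * i + 2]))
             for i in range(k)]
    return MixtureFit(components=comps, r2=float(r2))


def _fit_k(curve: DensityCurve, k: int,
           warm: Optional["MixtureFit"] = None) -> Optional[MixtureFit]:
    """Best of peak-based and warm-start (component-splitting) inits."""
    candidates = [_fit_once(curve, _initial_params(curve, k))]
    if warm is not None and warm.n_components == k - 1:
        candidates.extend(_fit_once(curve, p0) for p0 in _split_inits(warm, curve))
    candidates = [c for c in candidates if c is not None]
    if not candidates:
        return None
    return max(candidates, key=lambda f: f.r2)


def fit_mixture(curve: DensityCurve, r2_threshold: float = R2_THRESHOLD,
                max_components: int = MAX_COMPONENTS,
                n_components: Optional[int] = None,
                improvement_factor: float = IMPROVEMENT_FACTOR) -> MixtureFit:
    """Decompose a density curve into Gaussian components.

    With ``n_components`` given, exactly that many components are fitted
    (the goodness threshold still applies).  Otherwise the component number
    is selected automatically: smallest k with R² ≥ ``r2_threshold`` such
    that one more component does not cut the residual sum of squares by
    ``improvement_factor`` or more.
    """
    if n_components is not None:
        warm = None
        fit = None
        for k in range(1, n_components + 1):
            fit = _fit_k(curve, k, warm=warm)
            warm = fit if fit is not None else warm
        if fit is None:
            raise FitFailureError(f"least-squares fit with {n_components} components failed")
        if fit.r2 < r2_threshold:
            raise FitFailureError(
                f"fit with {n_components} components reached R²={fit.r2:.4f} "
                f"< {r2_threshold}", best_fit=fit)
        return fit

    best: Optional[MixtureFit] = None
    fits: dict[int, Optional[MixtureFit]] = {}
    warm: Optional[MixtureFit] = None
    k = 1
    while k <= max_components:
        fit = fits.get(k) or _fit_k(curve, k, warm=warm)
        fits[k] = fit
        warm = fit or warm
        if fit is not None:
            if best is None or fit.r2 > best.r2:
                best = fit
            if fit.r2 >= R2_SATURATED:
                return fit
            if fit.r2 >= r2_threshold:
                if k == max_components:
                    return fit
                nxt = _fit_k(curve, k + 1, warm=fit)
                fits[k + 1] = nxt
                ss_k = 1.0 - fit.r2
                ss_n = 1.0 - nxt.r2 if nxt is not None else ss_k
                if nxt is None or ss_n > ss_k / improvement_factor:
                    return fit
        k += 1
    raise FitFailureError(
        f"no fit with <= {max_components} components reached R² >= {r2_threshold}",
        best_fit=best)


def assign_events(fit: MixtureFit, expected_events: Sequence[str]) -> dict:
    """Match fitted components to named events by ascending mean against the
    expected ordering (youngest event first)."""
    if fit.n_components != len(expected_events):
        raise ValueError(
            f"ambiguous assignment: {fit.n_components} components for "
            f"{len(expected_events)} expected events {list(expected_events)}")
    comps = sorted(fit.components, key=lambda c: c.mean)
    return {ev: c for ev, c in zip(expected_events, comps)}


def density_to_frame(curve: DensityCurve) -> pd.DataFrame:
    return pd.DataFrame({"ks": curve.grid, "density": curve.density})
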