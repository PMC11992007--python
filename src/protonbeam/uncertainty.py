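"""Parametric uncertainty in the Bragg-Kleeman parameters (alpha, p).

alpha and p are modelled as independent Gaussians.  Three built-in cases
set the standard deviations: *absolute* (1e-4 each), *relative* (1% of the
means) and *empirical* (published 95% half-widths divided by 1.96, treating
the intervals as +/- 1.96 sigma of a normal).

Two complementary analyses are provided:

* local sensitivity at characteristic depths (proximal half-way point A,
  Bragg peak B, steepest distal gradient C): dose contours over the
  +/- 2 sigma phase plane and the active-subspace direction, i.e. the
  normalised dose gradient in sigma-standardised coordinates, along which
  the dose varies most;
* global Monte-Carlo propagation: empirical per-depth quantile bands for
  the dose curve and quantile intervals for the Bragg-peak depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .beam import Spectrum
from .dosimetry import DepthCurve, _integral_us, _refine_peak, peak_depth
from .medium import MediumModel
from .units import UNIT_DOSE_MEV_G

__all__ = [
    "ParameterDistribution",
    "EnsembleResult",
    "case_sigmas",
    "locate_points",
    "sensitivity_grid",
    "active_direction",
    "mc_dose_bands",
    "mc_peak_bands",
    "joint_exceedance_probability",
]

CASES = ("absolute", "relative", "empirical")


def case_sigmas(case: str, medium: MediumModel) -> tuple[float, float]:
    """Standard deviations (sigma_alpha, sigma_p) for a named case.

    absolute: (1e-4, 1e-4); relative: 1% of the medium means; empirical:
    the medium's 95% half-widths scaled by 1/1.96.
    """
    if case == "absolute":
        return (1e-4, 1e-4)
    if case == "relative":
        return (0.01 * medium.alpha, 0.01 * medium.p)
    if case == "empirical":
        if medium.alpha_halfwidth is None or medium.p_halfwidth is None:
            raise ValueError(
                f"medium {medium.name!r} has no published parameter "
                "uncertainties; the empirical case is unavailable"
            )
        return (medium.alpha_halfwidth / 1.96, medium.p_halfwidth / 1.96)
    raise ValueError(f"unknown case {case!r}; choose from {CASES}")


@dataclass(frozen=True)
class ParameterDistribution:
    """Independent normal distributions for alpha and p."""

    mu_alpha: float
    mu_p: float
    sigma_alpha: float
    sigma_p: float
    case: str = "custom"

    def __post_init__(self) -> None:
        if self.sigma_alpha < 0 or self.sigma_p < 0:
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_case(cls, case: str, medium: MediumModel) -> "ParameterDistribution":
        sa, sp = case_sigmas(case, medium)
        return cls(medium.alpha, medium.p, sa, sp, case=case)

    def sample(self, n: int, rng: np.random.Generator,
               max_redraws: int = 100) -> tuple[np.ndarray, np.ndarray, int]:
        """Draw n (alpha, p) pairs, rejecting non-physical tails.

        Draws with alpha <= 0 or p <= 1 (possible far in the tails) are
        redrawn; the rejection count is returned.  At the shipped sigmas
        the rejection rate is essentially zero.
        """
        alpha = rng.normal(self.mu_alpha, self.sigma_alpha, size=n)
        p = rng.normal(self.mu_p, self.sigma_p, size=n)
        rejected = 0
        for _ in range(max_redraws):
            bad = (alpha <= 0.0) | (p <= 1.0)
            nbad = int(bad.sum())
            if nbad == 0:
                break
            rejected += nbad
            alpha[bad] = rng.normal(self.mu_alpha, self.sigma_alpha, size=nbad)
            p[bad] = rng.normal(self.mu_p, self.sigma_p, size=nbad)
        else:
            raise RuntimeError("rejection sampling failed to converge")
        return alpha, p, rejected


class CharacteristicPoints(NamedTuple):
    a: float
    b: float
    c: float


def locate_points(curve: DepthCurve) -> CharacteristicPoints:
    """Characteristic depths of a Bragg curve.

    A is midway between entrance and peak, B is the peak, C is the depth of
    the steepest (most negative) gradient, which for a Bragg curve lies on
    the distal falloff.
    """
    zp, flat = peak_depth(curve, return_flag=True)
    if flat:
        raise ValueError("curve is flat; characteristic points undefined")
    deriv = np.gradient(curve.values, curve.z)
    c = float(curve.z[int(np.argmin(deriv))])
    return CharacteristicPoints(a=0.5 * zp, b=zp, c=c)


def _dose_at(alpha, p, z, spectrum: Spectrum, rho: float, n_nodes: int):
    return _integral_us(alpha, p, z, spectrum, n_nodes) / rho


def sensitivity_grid(spectrum: Spectrum, z: float, dist: ParameterDistribution,
                     n_grid: int = 21, rho: float = 1.0,
                     n_nodes: int = 128) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dose D(z; alpha, p) on the tensor grid spanning [mu +/- 2 sigma]^2.

    Returns (alphas, ps, dose) with dose[i, j] = D(z; alphas[i], ps[j]),
    covering the 95% confidence square of the parameter plane.
    """
    if n_grid < 5:
        raise ValueError("n_grid must be at least 5")
    alphas = np.linspace(dist.mu_alpha - 2 * dist.sigma_alpha,
                         dist.mu_alpha + 2 * dist.sigma_alpha, n_grid)
    ps = np.linspace(dist.mu_p - 2 * dist.sigma_p,
                     dist.mu_p + 2 * dist.sigma_p, n_grid)
    dose = _dose_at(alphas[:, None], ps[None, :], z, spectrum, rho, n_nodes)
    return alphas, ps, np.asarray(dose, float)


@dataclass(frozen=True)
class ActiveDirection:
    """Dominant sensitivity direction in sigma-standardised (alpha, p) space."""

    direction: np.ndarray       # unit vector (alpha-component, p-component)
    gradient: np.ndarray        # dose gradient per standardised unit
    eigenvalues: np.ndarray     # eigenvalues of the gradient outer product
    eigenvectors: np.ndarray    # columns are eigenvectors
    degenerate: bool


def active_direction(spectrum: Spectrum, z: float, dist: ParameterDistribution,
                     fd_step: float = 0.1, rho: float = 1.0,
                     n_nodes: int = 128) -> ActiveDirection:
    """Gradient direction of D(z; alpha, p) at the mean, standardised by sigma.

    Central finite differences with step ``fd_step`` standard deviations per
    coordinate; the outer product of the gradient is rank one, so one
    eigenvalue is zero and the dominant eigenvector is the normalised
    gradient itself.
    """
    if fd_step <= 0:
        raise ValueError("fd_step must be positive")
    ha = fd_step * dist.sigma_alpha
    hp = fd_step * dist.sigma_p
    if ha == 0 or hp == 0:
        raise ValueError("degenerate distribution: zero sigma")
    d = lambda a, p: float(_dose_at(a, p, z, spectrum, rho, n_nodes))
    ga = (d(dist.mu_alpha + ha, dist.mu_p) - d(dist.mu_alpha - ha, dist.mu_p)) / (
        2.0 * fd_step)
    gp = (d(dist.mu_alpha, dist.mu_p + hp) - d(dist.mu_alpha, dist.mu_p - hp)) / (
        2.0 * fd_step)
    grad = np.array([ga, gp])
    norm = np.linalg.norm(grad)
    degenerate = norm == 0.0
    direction = grad / norm if not degenerate else np.zeros(2)
    outer = np.outer(grad, grad)
    eigvals, eigvecs = np.linalg.eigh(outer)
    # descending order
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    return ActiveDirection(direction=direction, gradient=grad,
                           eigenvalues=eigvals, eigenvectors=eigvecs,
                           degenerate=degenerate)


@dataclass
class EnsembleResult:
    """Monte-Carlo ensemble summary for dose curves or peak depths."""

    n_samples: int
    seed: int
    levels: tuple[float, ...]
    n_rejected: int = 0
    z: np.ndarray | None = None
    nominal_curve: DepthCurve | None = None
    lower: dict[float, np.ndarray] = field(default_factory=dict)
    upper: dict[float, np.ndarray] = field(default_factory=dict)
    peak_samples: np.ndarray | None = None
    peak_intervals: dict[float, tuple[float, float]] = field(default_factory=dict)
    nominal_peak: float | None = None

    def band_frame(self):
        import pandas as pd

        cols = {"z_cm": self.z, "nominal": self.nominal_curve.values}
        for lev in sorted(self.levels):
            pct = 100.0 * (1.0 - lev) / 2.0
            cols[f"q{pct:g}"] = self.lower[lev]
            cols[f"q{100.0 - pct:g}"] = self.upper[lev]
        return pd.DataFrame(cols)


def _sample_dose_matrix(spectrum: Spectrum, grid: np.ndarray,
                        dist: ParameterDistribution, n_samples: int,
                        rng: np.random.Generator, rho: float,
                        n_nodes: int, chunk: int) -> tuple[np.ndarray, int]:
    alpha, p, rejected = dist.sample(n_samples, rng)
    doses = np.empty((n_samples, grid.size))
    for start in range(0, n_samples, chunk):
        sl = slice(start, min(start + chunk, n_samples))
        doses[sl] = _dose_at(alpha[sl, None], p[sl, None], grid[None, :],
                             spectrum, rho, n_nodes)
    return doses, rejected


def mc_dose_bands(spectrum: Spectrum, grid: np.ndarray,
                  dist: ParameterDistribution, n_samples: int, seed: int,
                  levels: tuple[float, ...] = (0.68, 0.95), rho: float = 1.0,
                  n_nodes: int = 128, chunk: int = 64) -> EnsembleResult:
    """Per-depth empirical quantile bands for D(z; alpha, p).

    Draws (alpha, p) from ``dist``, recomputes the analytic dose curve per
    draw, and reports linear-interpolation empirical quantiles at each
    depth alongside the nominal curve D(z; mu_alpha, mu_p).  Seeded and
    reproducible.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 Monte-Carlo samples")
    rng = np.random.default_rng(seed)
    doses, rejected = _sample_dose_matrix(spectrum, grid, dist, n_samples, rng,
                                          rho, n_nodes, chunk)
    nominal_vals = np.atleast_1d(
        _dose_at(dist.mu_alpha, dist.mu_p, grid, spectrum, rho, n_nodes))
    nominal = DepthCurve(grid, nominal_vals, UNIT_DOSE_MEV_G)
    res = EnsembleResult(n_samples=n_samples, seed=seed, levels=tuple(levels),
                         n_rejected=rejected, z=grid, nominal_curve=nominal)
    for lev in levels:
        tail = (1.0 - lev) / 2.0
        res.lower[lev] = np.quantile(doses, tail, axis=0)
        res.upper[lev] = np.quantile(doses, 1.0 - tail, axis=0)
    return res


def mc_peak_bands(spectrum: Spectrum, grid: np.ndarray,
                  dist: ParameterDistribution, n_samples: int, seed: int,
                  levels: tuple[float, ...] = (0.68, 0.95), rho: float = 1.0,
                  n_nodes: int = 128, chunk: int = 64) -> EnsembleResult:
    """Empirical quantile intervals for the Bragg-peak depth z_peak.

    Each sampled dose curve is reduced to its (parabolically refined) peak
    depth; intervals are empirical quantiles of that sample.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 Monte-Carlo samples")
    rng = np.random.default_rng(seed)
    doses, rejected = _sample_dose_matrix(spectrum, grid, dist, n_samples, rng,
                                          rho, n_nodes, chunk)
    idx = np.argmax(doses, axis=1)
    peaks = _refine_peak(grid, doses, idx)
    nominal_vals = np.atleast_1d(
        _dose_at(dist.mu_alpha, dist.mu_p, grid, spectrum, rho, n_nodes))
    nominal = DepthCurve(grid, nominal_vals, UNIT_DOSE_MEV_G)
    res = EnsembleResult(n_samples=n_samples, seed=seed, levels=tuple(levels),
                         n_rejected=rejected, z=grid, nominal_curve=nominal,
                         peak_samples=peaks,
                         nominal_peak=peak_depth(nominal))
    for lev in levels:
        tail = (1.0 - lev) / 2.0
        res.peak_intervals[lev] = (float(np.quantile(peaks, tail)),
                                   float(np.quantile(peaks, 1.0 - tail)))
    return res


def joint_exceedance_probability(level: float = 0.95, k: int = 2) -> float:
    """Probability of simultaneous exceedance of the two-sided CI in k
    independent parameters under the 2-sigma = 95%-CI convention.

    For the default level this is 0.05**2 = 0.25%.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    return (1.0 - level) ** k
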