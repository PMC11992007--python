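"""Inflow energy spectra and the closed-form fluence solution.

The 1D transport problem

    d/dz u(z, E) + d/dE [ S(E) u(z, E) ] = 0,
    u(0, E) = g(E),          u(z, E_max) = 0,

with Bragg-Kleeman stopping power is hyperbolic; integrating along the
characteristics ``E**p = E0**p - z/alpha`` gives the closed form

    u(z, E) = (E**p + z/alpha)**((1-p)/p) * g((E**p + z/alpha)**(1/p)) * E**(p-1).

The inflow spectrum ``g`` is represented as a non-negative weighted sum of
(truncated) Gaussian components on an energy window, with an overall
normalisation constant tying the window integral to a prescribed total
fluence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from scipy.special import erf

__all__ = [
    "EnergyWindow",
    "GaussianComponent",
    "Spectrum",
    "make_gaussian_spectrum",
    "FluenceField",
    "DEFAULT_WINDOW",
]


@dataclass(frozen=True)
class EnergyWindow:
    """Admissible particle energies [e_min, e_max] in MeV.

    The lower edge must be positive in practice because the Bragg-Kleeman
    stopping power diverges at E = 0; the default 0.1 MeV corresponds to a
    residual range of well under a micrometre in water, negligible on the
    centimetre scales of the model.
    """

    e_min: float = 0.1
    e_max: float = 250.0

    def __post_init__(self) -> None:
        if not 0 <= self.e_min < self.e_max:
            raise ValueError(
                f"require 0 <= e_min < e_max, got [{self.e_min}, {self.e_max}]"
            )

    def contains(self, e) -> np.ndarray:
        e = np.asarray(e, dtype=float)
        return (e >= self.e_min) & (e <= self.e_max)


DEFAULT_WINDOW = EnergyWindow()


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian beamlet: intensity * exp(-(E - energy)**2 / (2 sigma**2))."""

    energy: float
    sigma: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.energy > 0:
            raise ValueError("principal energy must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.weight < 0:
            raise ValueError("component weight must be non-negative")


_SQRT2 = np.sqrt(2.0)
_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


@dataclass(frozen=True)
class Spectrum:
    """Inflow spectrum g(E): a Gaussian mixture truncated to an energy window.

    ``g(E) = norm * sum_i w_i exp(-(E - E_i)**2 / (2 sigma_i**2))`` inside the
    window and 0 outside.  ``norm`` is the global normalisation constant C;
    construct via :func:`make_gaussian_spectrum` to pin the window integral
    to a total fluence.
    """

    components: tuple[GaussianComponent, ...]
    window: EnergyWindow = DEFAULT_WINDOW
    norm: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.norm < 0:
            raise ValueError("normalisation constant must be non-negative")

    def __call__(self, e) -> np.ndarray:
        """Evaluate g(E) (protons/cm^2/MeV); zero outside the window."""
        e = np.asarray(e, dtype=float)
        out = np.zeros_like(e, dtype=float)
        for c in self.components:
            out += c.weight * np.exp(-((e - c.energy) ** 2) / (2.0 * c.sigma**2))
        out *= self.norm
        out = np.where(self.window.contains(e), out, 0.0)
        return out

    def band_integral(self, lo=None, hi=None) -> np.ndarray | float:
        """Exact integral of g over [lo, hi] (clipped to the window).

        Closed form for the truncated Gaussian mixture via erf; ``lo``/``hi``
        may be arrays (broadcast).
        """
        lo = self.window.e_min if lo is None else lo
        hi = self.window.e_max if hi is None else hi
        lo = np.clip(np.asarray(lo, dtype=float), self.window.e_min, self.window.e_max)
        hi = np.clip(np.asarray(hi, dtype=float), self.window.e_min, self.window.e_max)
        total = np.zeros(np.broadcast(lo, hi).shape, dtype=float)
        for c in self.components:
            a = (lo - c.energy) / (c.sigma * _SQRT2)
            b = (hi - c.energy) / (c.sigma * _SQRT2)
            total += c.weight * c.sigma * _SQRT_HALF_PI * (erf(b) - erf(a))
        out = self.norm * np.clip(total, 0.0, None)
        return out.item() if np.ndim(out) == 0 else out

    def component_terms(self):
        """Contributing Gaussian terms as (lo, hi, amplitude, energy, sigma).

        ``amplitude = norm * weight`` and [lo, hi] is the component's
        8-sigma support clipped to the window; terms with no mass inside
        the window are dropped.  Depth quadratures integrate each term on
        its own support, which keeps narrow, well-separated components
        resolved.
        """
        if self.norm == 0.0:
            return
        for c in self.components:
            if c.weight <= 0:
                continue
            lo = max(c.energy - 8.0 * c.sigma, self.window.e_min)
            hi = min(c.energy + 8.0 * c.sigma, self.window.e_max)
            if lo >= hi:
                continue
            yield lo, hi, self.norm * c.weight, c.energy, c.sigma

    @property
    def support(self) -> tuple[float, float]:
        """Effective energy support [lo, hi]: component 8-sigma envelopes
        intersected with the window.  Mass outside is below 1e-15 of the
        total and is ignored by the depth quadratures."""
        comps = [c for c in self.components if c.weight > 0]
        if not comps or self.norm == 0.0:
            return (self.window.e_min, self.window.e_min)
        lo = min(c.energy - 8.0 * c.sigma for c in comps)
        hi = max(c.energy + 8.0 * c.sigma for c in comps)
        lo = min(max(lo, self.window.e_min), self.window.e_max)
        hi = max(min(hi, self.window.e_max), self.window.e_min)
        return (lo, hi)

    @property
    def total_fluence(self) -> float:
        """Integral of g over the full window, protons/cm^2."""
        return float(self.band_integral())

    def shortest_populated_range(self, medium, mass_tol: float = 1e-6) -> float:
        """Depth before which essentially no particle has stopped.

        Range of the lowest energy below which only a fraction ``mass_tol``
        of the spectrum mass lies (5-sigma tails per component as a guard).
        """
        lows = [max(self.window.e_min, c.energy - 5.0 * c.sigma)
                for c in self.components if c.weight > 0]
        if not lows:
            return np.inf
        return medium.range_from_energy(min(lows))

    def write_csv(self, path: str | Path, n: int = 1000) -> None:
        """Sample g on a uniform grid over the window and write E_MeV,g_per_MeV."""
        e = np.linspace(self.window.e_min, self.window.e_max, n)
        g = self(e)
        header = (
            f"# spectrum: {len(self.components)} components, "
            f"window [{self.window.e_min}, {self.window.e_max}] MeV, "
            f"norm {self.norm!r}\nE_MeV,g_per_MeV\n"
        )
        body = "\n".join(f"{ei:.8g},{gi:.10g}" for ei, gi in zip(e, g))
        Path(path).write_text(header + body + "\n")


def make_gaussian_spectrum(e0: float, epsilon: float, fluence: float,
                           window: EnergyWindow = DEFAULT_WINDOW) -> Spectrum:
    """Single-Gaussian inflow spectrum with relative energy spread.

    Parameters
    ----------
    e0 : float
        Principal energy, MeV; must lie so that the window retains Gaussian
        mass (within 6 sigma of the window).
    epsilon : float
        Relative energy spread; the Gaussian std is ``sigma = epsilon * e0``.
    fluence : float
        Total fluence Phi, protons/cm^2.  The normalisation constant C is
        computed by adaptive numerical quadrature of the raw Gaussian over
        the window so that the window integral of g equals Phi exactly
        (truncated constant, not the untruncated sigma*sqrt(2*pi)).
    """
    if epsilon <= 0:
        raise ValueError("relative spread epsilon must be positive")
    if fluence < 0:
        raise ValueError("total fluence must be non-negative")
    sigma = epsilon * e0
    if e0 + 6.0 * sigma < window.e_min or e0 - 6.0 * sigma > window.e_max:
        raise ValueError(
            "energy window excludes essentially all Gaussian mass "
            f"(E0 = {e0} MeV more than 6 sigma outside [{window.e_min}, {window.e_max}])"
        )
    comp = GaussianComponent(energy=e0, sigma=sigma, weight=1.0)
    if fluence == 0.0:
        return Spectrum((comp,), window, norm=0.0)
    # Integrate over the (clipped) 10-sigma support: outside it the mass is
    # ~1e-23 of the total, and adaptive quadrature on the full window can
    # miss an extremely narrow peak entirely.
    lo = max(window.e_min, e0 - 10.0 * sigma)
    hi = min(window.e_max, e0 + 10.0 * sigma)
    raw, _ = quad(
        lambda e: np.exp(-((e - e0) ** 2) / (2.0 * sigma**2)),
        lo, hi, epsabs=0.0, epsrel=1e-12, limit=200,
    )
    if raw <= 0:
        raise ValueError("spectrum normalisation integral vanished")
    return Spectrum((comp,), window, norm=fluence / raw)


@dataclass(frozen=True)
class FluenceField:
    """Closed-form fluence u(z, E) for a medium and an inflow spectrum."""

    medium: "MediumModel"  # noqa: F821 - forward ref, see medium module
    spectrum: Spectrum

    def fluence(self, z, e) -> np.ndarray:
        """Evaluate u(z, E), protons/cm^2/MeV.

        Implements the characteristics solution; returns 0 whenever the
        mapped initial energy ``(E**p + z/alpha)**(1/p)`` leaves the window
        (the outflow boundary condition).
        """
        z = np.asarray(z, dtype=float)
        e = np.asarray(e, dtype=float)
        if np.any(z < 0):
            raise ValueError("depth must be non-negative")
        if np.any(e <= 0):
            raise ValueError("fluence requires E > 0")
        p = self.medium.p
        alpha = self.medium.alpha
        mapped_p = e**p + z / alpha
        e0 = mapped_p ** (1.0 / p)
        out = mapped_p ** ((1.0 - p) / p) * self.spectrum(e0) * e ** (p - 1.0)
        return out.item() if out.ndim == 0 else out

    __call__ = fluence
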