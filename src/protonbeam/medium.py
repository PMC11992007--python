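"""Homogeneous media and the Bragg-Kleeman range-energy relationship.

A proton of initial energy ``E0`` (MeV) entering a homogeneous medium
penetrates to a range ``R0 = alpha * E0**p`` (cm), the Bragg-Kleeman power
law.  Everything else in the transport model follows from this relation:
the residual energy at depth ``z`` is ``E(z) = ((R0 - z)/alpha)**(1/p)``
and the stopping power (energy loss per unit path length) is
``S(E) = E**(1-p) / (alpha * p)``, which grows without bound as the proton
slows down -- the origin of the Bragg peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "MediumModel",
    "MEDIA",
    "get_medium",
    "load_media",
    "range_from_energy",
    "energy_from_range",
    "energy_at_depth",
    "stopping_power",
]


@dataclass(frozen=True)
class MediumModel:
    """Bragg-Kleeman parameters for one homogeneous medium.

    Parameters
    ----------
    name : str
        Label for the medium.
    alpha : float
        Range coefficient, cm * MeV**(-p).  Strictly positive.
    p : float
        Range exponent, dimensionless, in the admissible band [1, 2].
    rho : float
        Mass density, g/cm^3.
    alpha_halfwidth, p_halfwidth : float, optional
        95% confidence half-widths on ``alpha`` and ``p`` where an
        empirical uncertainty estimate exists (water only in the shipped
        registry).
    """

    name: str
    alpha: float
    p: float
    rho: float = 1.0
    alpha_halfwidth: float | None = None
    p_halfwidth: float | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 1.0 <= self.p <= 2.0:
            raise ValueError(f"p must lie in [1, 2], got {self.p}")
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")

    # Convenience method forms of the module-level operations.
    def range_from_energy(self, e0):
        return range_from_energy(e0, self)

    def energy_from_range(self, r):
        return energy_from_range(r, self)

    def energy_at_depth(self, z, e0):
        return energy_at_depth(z, e0, self)

    def stopping_power(self, e):
        return stopping_power(e, self)

    def with_parameters(self, alpha: float, p: float) -> "MediumModel":
        """Copy of this medium with perturbed Bragg-Kleeman parameters."""
        return MediumModel(self.name, alpha, p, self.rho,
                           self.alpha_halfwidth, self.p_halfwidth)


def range_from_energy(e0, medium: MediumModel):
    """Proton range ``R0 = alpha * E0**p`` in cm.  Strictly increasing in E0."""
    e0 = np.asarray(e0, dtype=float)
    if np.any(e0 < 0):
        raise ValueError("energy must be non-negative")
    out = medium.alpha * e0 ** medium.p
    return out.item() if out.ndim == 0 else out


def energy_from_range(r, medium: MediumModel):
    """Initial energy ``(R/alpha)**(1/p)`` in MeV; exact inverse of range."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("range must be non-negative")
    out = (r / medium.alpha) ** (1.0 / medium.p)
    return out.item() if out.ndim == 0 else out


def energy_at_depth(z, e0, medium: MediumModel):
    """Residual beam energy at depth ``z`` for entrance energy ``e0``.

    Returns 0 beyond the range (the proton has stopped), so downstream
    dose and LET integrands vanish smoothly rather than raising.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    r0 = range_from_energy(e0, medium)
    residual = np.clip(r0 - z, 0.0, None)
    out = (residual / medium.alpha) ** (1.0 / medium.p)
    return out.item() if out.ndim == 0 else out


def stopping_power(e, medium: MediumModel):
    """Bragg-Kleeman stopping power ``S(E) = E**(1-p) / (alpha p)`` in MeV/cm.

    Diverges as E -> 0 for p > 1, hence strictly positive energies only.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0):
        raise ValueError("stopping power requires E > 0 (S diverges at E = 0)")
    out = e ** (1.0 - medium.p) / (medium.alpha * medium.p)
    return out.item() if out.ndim == 0 else out


#: Shipped registry of range-energy parameters.  The water entry carries
#: empirical 95% half-widths from comparing published parameterisations.
MEDIA: dict[str, MediumModel] = {
    "water": MediumModel("water", alpha=0.00246, p=1.75, rho=1.0,
                         alpha_halfwidth=0.00025, p_halfwidth=0.02),
    "muscle": MediumModel("muscle", alpha=0.0021, p=1.75),
    "bone": MediumModel("bone", alpha=0.0011, p=1.77),
    "lung": MediumModel("lung", alpha=0.0033, p=1.74),
    "water_bortfeld": MediumModel("water_bortfeld", alpha=0.0022, p=1.77,
                                  rho=1.0),
}


def get_medium(name: str) -> MediumModel:
    try:
        return MEDIA[name]
    except KeyError:
        raise KeyError(
            f"unknown medium {name!r}; known media: {sorted(MEDIA)}"
        ) from None


_MEDIUM_KEYS = {"alpha", "p", "rho", "alpha_halfwidth", "p_halfwidth"}


def load_media(path: str | Path) -> dict[str, MediumModel]:
    """Load a media registry from a YAML or JSON mapping of name -> params.

    Each entry must provide ``alpha`` and ``p``; ``rho`` defaults to 1.
    Unknown keys are rejected.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("media file must map names to parameter mappings")
    registry = {}
    for name, params in data.items():
        if not isinstance(params, dict):
            raise ValueError(f"medium {name!r}: expected a mapping of parameters")
        unknown = set(params) - _MEDIUM_KEYS
        if unknown:
            raise ValueError(f"medium {name!r}: unknown keys {sorted(unknown)}")
        if "alpha" not in params or "p" not in params:
            raise ValueError(f"medium {name!r}: 'alpha' and 'p' are required")
        registry[name] = MediumModel(name=name, **params)
    return registry
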