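"""Spread-out Bragg peak (SOBP) treatment planning.

A treatment plan superposes ``N_y`` Gaussian basis beams with non-negative
intensities ``y``.  Because the transport model is linear in the inflow
spectrum, the dose is a linear combination of precomputed unit-weight
influence profiles, ``D(y, z) = sum_i y_i D_i(z)``, and matching a target
profile ``T(z)`` under a spatial weighting ``w(z)`` is the discrete
weighted least-squares problem

    L(y) = sum_{j>=1} 1/2 w(z_j) (D(y, z_j) - T(z_j))^2 (z_j - z_{j-1}),

minimised over the admissible set ``{y : 0 <= y_i <= ub}``.  The
LET-weighted (biological) dose objective stays in this quadratic family via
the identity ``D L_D = sum_i y_i Q_i`` (the S^2-weighted profiles), whereas
the survival-fraction objective is genuinely nonlinear.

The module follows the statsmodels idiom: :class:`TreatmentPlan` is the
model, :meth:`TreatmentPlan.fit` returns :class:`PlanResults` carrying the
optimal weights, the achieved cost and diagnostics, with ``summary()`` and
curve accessors hanging off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import lsq_linear, minimize, nnls

from .beam import DEFAULT_WINDOW, EnergyWindow, GaussianComponent
from .dosimetry import (
    DepthCurve,
    influence_profiles,
)
from .medium import MediumModel
from .radiobiology import CellLine, survival_proton
from .units import (
    MEV_PER_CM_TO_KEV_PER_UM,
    UNIT_DIMENSIONLESS,
    UNIT_DOSE_GY,
    UNIT_DOSE_MEV_G,
    UNIT_LET,
)

__all__ = [
    "RegionPartition",
    "select_basis_energies",
    "build_weight_function",
    "TreatmentPlan",
    "PlanResults",
    "evaluate_plan",
]

OBJECTIVES = ("dose", "biological_dose", "survival_fraction")


@dataclass(frozen=True)
class RegionPartition:
    """Tumour interval, optional organ-at-risk interval; healthy elsewhere."""

    tumour: tuple[float, float]
    oar: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        zp, zd = self.tumour
        if not 0 <= zp < zd:
            raise ValueError("tumour interval must satisfy 0 <= z_prox < z_dist")
        if self.oar is not None:
            a, b = self.oar
            if not a < b:
                raise ValueError("OAR interval must be non-empty")
            if a < zd and b > zp:
                raise ValueError("tumour and OAR intervals must be disjoint")

    def tumour_mask(self, z: np.ndarray) -> np.ndarray:
        zp, zd = self.tumour
        return (z >= zp) & (z <= zd)

    def oar_mask(self, z: np.ndarray) -> np.ndarray:
        if self.oar is None:
            return np.zeros_like(z, dtype=bool)
        a, b = self.oar
        return (z > a) & (z <= b)


def select_basis_energies(n: int, range_interval: tuple[float, float],
                          sigma2: float, medium: MediumModel,
                          window: EnergyWindow = DEFAULT_WINDOW,
                          ) -> list[GaussianComponent]:
    """Basis beams whose ranges are equally spaced on ``range_interval``.

    Each principal energy is the Bragg-Kleeman inverse ``(R/alpha)**(1/p)``
    of one of n equally spaced ranges; all beams share variance ``sigma2``
    (MeV^2) and unit weight.
    """
    a, b = range_interval
    if n < 1:
        raise ValueError("need at least one basis beam")
    if not 0 < a <= b:
        raise ValueError("range interval must satisfy 0 < a <= b")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    ranges = np.linspace(a, b, n) if n > 1 else np.array([a])
    energies = medium.energy_from_range(ranges)
    energies = np.atleast_1d(energies)
    sigma = float(np.sqrt(sigma2))
    if np.any(~window.contains(energies)):
        raise ValueError(
            "requested ranges need energies outside the window "
            f"[{window.e_min}, {window.e_max}] MeV"
        )
    return [GaussianComponent(energy=float(e), sigma=sigma, weight=1.0)
            for e in energies]


def build_weight_function(regions: RegionPartition, w_tumour: float,
                          w_oar: float, w_healthy: float,
                          z: np.ndarray) -> np.ndarray:
    """Piecewise-constant spatial weighting w(z) on the grid."""
    if min(w_tumour, w_oar, w_healthy) < 0:
        raise ValueError("weights must be non-negative")
    w = np.full_like(np.asarray(z, float), w_healthy)
    w[regions.oar_mask(z)] = w_oar
    w[regions.tumour_mask(z)] = w_tumour
    return w


def _target_array(target, regions: RegionPartition, z: np.ndarray) -> np.ndarray:
    if callable(target):
        return np.asarray(target(z), dtype=float)
    t = np.asarray(target, dtype=float)
    if t.ndim == 0:
        return np.where(regions.tumour_mask(z), float(t), 0.0)
    if t.shape != z.shape:
        raise ValueError("target array must match the depth grid")
    return t


class TreatmentPlan:
    """SOBP planning model: basis beams, geometry, target and objective.

    Parameters
    ----------
    basis : sequence of GaussianComponent
        Unit-weight basis beams (use :func:`select_basis_energies`).
    regions : RegionPartition
        Tumour and optional OAR intervals.
    medium : MediumModel
    target : float, array or callable, default 1.0
        Target profile; a scalar means that value inside the tumour and 0
        elsewhere.  For the survival objective this is the target survival
        fraction (scalar targets then mean ``target`` inside the tumour and
        1 -- no cell kill -- elsewhere).
    weights : (w_tumour, w_oar, w_healthy), default (1, 0, 0)
    objective : {'dose', 'biological_dose', 'survival_fraction'}
    cell : CellLine, required for the biological objectives.
    grid : array, optional
        Depth grid; default 1200 uniform points on [0, z_dist + 2] cm.
    upper_bound : float, optional
        Upper bound on each beam weight (machine limits); lower bound is 0.
    dose_scale : float, default 1.0
        Multiplier taking the raw influence dose (MeV/g for unit-weight
        beams) to the unit the target is expressed in.  The shipped
        examples use unit-free relative dose, so the default leaves the
        scale arbitrary; survival-fraction plans must supply a scale that
        makes ``dose_scale * D`` a dose in Gy.
    """

    def __init__(self, basis: Sequence[GaussianComponent],
                 regions: RegionPartition, medium: MediumModel,
                 target=1.0, weights: tuple[float, float, float] = (1.0, 0.0, 0.0),
                 objective: str = "dose", cell: CellLine | None = None,
                 grid: np.ndarray | None = None,
                 window: EnergyWindow = DEFAULT_WINDOW,
                 upper_bound: float | None = None,
                 dose_scale: float = 1.0,
                 n_nodes: int = 192):
        if objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if objective != "dose" and cell is None:
            raise ValueError(f"objective {objective!r} requires a cell line")
        self.basis = list(basis)
        self.regions = regions
        self.medium = medium
        self.objective = objective
        self.cell = cell
        self.window = window
        self.upper_bound = upper_bound
        self.dose_scale = float(dose_scale)
        if grid is None:
            grid = np.linspace(0.0, regions.tumour[1] + 2.0, 1200)
        self.grid = np.asarray(grid, dtype=float)
        self.w = build_weight_function(regions, *weights, self.grid)
        self.target = _target_array(target, regions, self.grid)
        if objective == "survival_fraction":
            # outside the tumour a scalar target means "no prescribed kill"
            if np.ndim(target) == 0 and not callable(target):
                self.target = np.where(regions.tumour_mask(self.grid),
                                       float(target), 1.0)
            if np.any((self.target <= 0) | (self.target > 1)):
                raise ValueError("survival targets must lie in (0, 1]")
        # Influence matrices, (n_z, n_beams); D in MeV/g per unit weight.
        d_mat, q_mat = influence_profiles(self.basis, medium, self.grid,
                                          window=window, n_nodes=n_nodes)
        self.d_matrix = d_mat.T.copy()
        self.q_matrix = q_mat.T.copy()
        self._dz = np.diff(self.grid)

    # -- assembly -----------------------------------------------------------

    @property
    def n_beams(self) -> int:
        return len(self.basis)

    def _response_matrix(self) -> np.ndarray:
        """Matrix whose y-linear combination is compared with the target."""
        if self.objective == "biological_dose":
            lam_ratio = self.cell.lam / self.cell.c_xray
            return (self.d_matrix
                    + lam_ratio * MEV_PER_CM_TO_KEV_PER_UM * self.q_matrix)
        return self.d_matrix

    def dose(self, y: np.ndarray) -> np.ndarray:
        """Physical dose profile for weights y (target units)."""
        return self.dose_scale * (self.d_matrix @ np.asarray(y, float))

    def dose_let(self, y: np.ndarray) -> np.ndarray:
        """Dose-averaged LET profile for weights y, keV/um (0 where no dose)."""
        num = self.q_matrix @ np.asarray(y, float)
        den = self.d_matrix @ np.asarray(y, float)
        out = np.zeros_like(den)
        big = den > 1e-12 * max(den.max(), 1e-300)
        np.divide(num, den, out=out, where=big)
        return out * MEV_PER_CM_TO_KEV_PER_UM

    def survival(self, y: np.ndarray) -> np.ndarray:
        """Survival-fraction profile; requires dose_scale to yield Gy."""
        if self.cell is None:
            raise ValueError("survival evaluation requires a cell line")
        return survival_proton(self.dose(y), self.dose_let(y), self.cell)

    # -- cost ---------------------------------------------------------------

    def _quad_system(self) -> tuple[np.ndarray, np.ndarray]:
        """Row-scaled design matrix / target of the discrete least squares.

        L(y) = 1/2 || A y - b ||^2 with rows scaled by sqrt(w_j dz_j); the
        j = 0 entrance point carries no quadrature weight.
        """
        scale = np.sqrt(self.w[1:] * self._dz)
        m = self._response_matrix()[1:] * self.dose_scale
        a = scale[:, None] * m
        b = scale * self.target[1:]
        return a, b

    def cost(self, y: np.ndarray) -> float:
        """Objective value L(y) for a weight vector."""
        y = np.asarray(y, dtype=float)
        if self.objective == "survival_fraction":
            resid = self.survival(y) - self.target
        else:
            resid = self.dose_scale * (self._response_matrix() @ y) - self.target
        return float(0.5 * np.sum(self.w[1:] * resid[1:] ** 2 * self._dz))

    def cost_zero(self) -> float:
        """Cost of the all-zero plan (the normaliser of the relative error)."""
        return self.cost(np.zeros(self.n_beams))

    # -- fitting ------------------------------------------------------------

    def fit(self, method: str = "quasi_newton", polish: bool = True,
            maxiter: int = 2000) -> "PlanResults":
        """Minimise the objective over the admissible set.

        method 'quasi_newton': bound-constrained L-BFGS-B from y = 0 with the
        analytic gradient, optionally polished by an exact least-squares
        solve on the identified active face (quadratic objectives only).
        method 'nnls': direct non-negative least squares on the row-scaled
        design matrix -- the exact solver for the quadratic objectives,
        kept as an independent cross-check oracle.
        """
        if self.objective == "survival_fraction":
            return self._fit_survival(maxiter=maxiter)
        if method not in ("quasi_newton", "nnls"):
            raise ValueError("method must be 'quasi_newton' or 'nnls'")
        a, b = self._quad_system()
        col = np.max(np.abs(a), axis=0)
        col[col == 0] = 1.0
        a_sc = a / col
        ub = self.upper_bound
        if method == "nnls":
            if ub is None:
                x, _ = nnls(a_sc, b, maxiter=10 * max(a_sc.shape))
                converged, nit = True, -1
            else:
                sol = lsq_linear(a_sc, b, bounds=(0.0, ub * col),
                                 tol=1e-14, max_iter=maxiter)
                x, converged, nit = sol.x, sol.success, sol.nit
            y = x / col
        else:
            gram = a_sc.T @ a_sc
            atb = a_sc.T @ b
            btb = b @ b

            def f(x):
                return 0.5 * (x @ gram @ x - 2.0 * atb @ x + btb)

            def jac(x):
                return gram @ x - atb

            bounds = [(0.0, None if ub is None else ub * c) for c in col]
            res = minimize(f, np.zeros(a_sc.shape[1]), jac=jac,
                           method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "ftol": 1e-18,
                                    "gtol": 1e-14, "maxfun": 10 * maxiter})
            x, converged, nit = res.x, bool(res.success), res.nit
            if polish and ub is None:
                x = self._polish_active_set(a_sc, b, x)
                # declare convergence from first-order (KKT) conditions:
                # vanishing gradient on free coordinates, non-negative on
                # the active bound
                grad = a_sc.T @ (a_sc @ x - b)
                gscale = max(np.abs(a_sc.T @ b).max(), 1e-300)
                free = x > 0
                converged = bool(
                    np.all(np.abs(grad[free]) <= 1e-8 * gscale)
                    and np.all(grad[~free] >= -1e-8 * gscale)
                )
            y = x / col
        cost = self.cost(y)
        return PlanResults(self, y, cost=cost, cost_zero=self.cost_zero(),
                           converged=bool(converged), n_iter=int(nit),
                           method=method)

    @staticmethod
    def _polish_active_set(a: np.ndarray, b: np.ndarray, x: np.ndarray,
                           max_rounds: int = 20) -> np.ndarray:
        """Exact least-squares refinement on the active face of [0, inf)^n.

        Repeatedly solves the unconstrained problem on the currently free
        coordinates, clipping any coordinate the solve drives negative, and
        frees bound coordinates whose KKT multiplier turns negative.
        """
        n = a.shape[1]
        free = x > 1e-10 * max(x.max(), 1.0)
        best = np.clip(x, 0.0, None)
        for _ in range(max_rounds):
            if free.any():
                sol, *_ = np.linalg.lstsq(a[:, free], b, rcond=None)
                if np.any(sol < 0):
                    trial = np.zeros(n)
                    trial[free] = np.clip(sol, 0.0, None)
                    free = trial > 0
                    best = trial
                    continue
                trial = np.zeros(n)
                trial[free] = sol
            else:
                trial = np.zeros(n)
            grad = a.T @ (a @ trial - b)
            viol = (~free) & (grad < -1e-12 * max(np.abs(grad).max(), 1.0))
            best = trial
            if not viol.any():
                break
            free = free | viol
        return best

    def _fit_survival(self, maxiter: int = 2000) -> "PlanResults":
        """Bound-constrained nonlinear fit of the survival-fraction cost.

        Slower than the quadratic objectives and potentially multi-modal:
        once the survival is near zero, extra dose is essentially free, so
        solutions can over-dose regions already below the target.
        """
        peak = np.max(self.d_matrix * self.dose_scale, axis=0)
        peak[peak == 0] = 1.0
        col = 1.0 / peak  # unit column scaling: x = y / col

        def f(x):
            return self.cost(x * col)

        ub = self.upper_bound
        bounds = [(0.0, None if ub is None else ub / c) for c in col]
        res = minimize(f, np.zeros(self.n_beams), method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-15})
        y = res.x * col
        return PlanResults(self, y, cost=float(res.fun),
                           cost_zero=self.cost_zero(),
                           converged=bool(res.success), n_iter=int(res.nit),
                           method="quasi_newton")


@dataclass
class PlanResults:
    """Fitted plan: optimal weights, achieved cost and diagnostics."""

    model: TreatmentPlan
    weights: np.ndarray
    cost: float
    cost_zero: float
    converged: bool
    n_iter: int
    method: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def relative_error(self) -> float:
        """L(y*) / L(0), the headline plan-quality number."""
        return self.cost / self.cost_zero if self.cost_zero > 0 else np.nan

    # -- assembled curves ---------------------------------------------------

    def dose_curve(self) -> DepthCurve:
        vals = self.model.dose(self.weights)
        units = UNIT_DOSE_GY if self.model.dose_scale != 1.0 else UNIT_DOSE_MEV_G
        return DepthCurve(self.model.grid, vals, units,
                          meta={"objective": self.model.objective})

    def dose_let_curve(self) -> DepthCurve:
        return DepthCurve(self.model.grid, self.model.dose_let(self.weights),
                          UNIT_LET)

    def biological_dose_curve(self, cell: CellLine | None = None) -> DepthCurve:
        cell = cell or self.model.cell
        if cell is None:
            raise ValueError("biological dose requires a cell line")
        d = self.model.dose(self.weights)
        let = self.model.dose_let(self.weights)
        vals = d * (1.0 + cell.lam / cell.c_xray * let)
        return DepthCurve(self.model.grid, vals, self.dose_curve().units)

    def survival_fraction_curve(self, cell: CellLine | None = None) -> DepthCurve:
        cell = cell or self.model.cell
        if cell is None:
            raise ValueError("survival requires a cell line")
        d = self.model.dose(self.weights)
        let = self.model.dose_let(self.weights)
        return DepthCurve(self.model.grid, survival_proton(d, let, cell),
                          UNIT_DIMENSIONLESS)

    def summary(self) -> str:
        m = self.model
        zp, zd = m.regions.tumour
        lines = [
            "SOBP treatment plan results",
            "=" * 60,
            f"objective:        {m.objective}",
            f"method:           {self.method}",
            f"basis beams:      {m.n_beams}",
            f"tumour interval:  [{zp:g}, {zd:g}] cm",
            f"OAR interval:     {m.regions.oar}",
            f"cost L(y*):       {self.cost:.6e}",
            f"cost L(0):        {self.cost_zero:.6e}",
            f"relative error:   {self.relative_error:.3e}",
            f"converged:        {self.converged} (iterations: {self.n_iter})",
            "-" * 60,
            f"{'beam':>4} {'E (MeV)':>10} {'range (cm)':>11} {'weight':>14}",
        ]
        for i, (c, y) in enumerate(zip(m.basis, self.weights)):
            rng = m.medium.range_from_energy(c.energy)
            lines.append(f"{i:>4} {c.energy:>10.3f} {rng:>11.4f} {y:>14.6e}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Dose profile with the target overlaid (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.grid, self.model.dose(self.weights), label="dose")
        ax.plot(self.model.grid, self.model.target, "--", label="target")
        ax.set_xlabel("depth z (cm)")
        ax.legend()
        return ax


def evaluate_plan(results: PlanResults, cell: CellLine | None = None) -> dict:
    """Region-level report for a fitted plan.

    Dose statistics inside the tumour and OAR, the worst in-tumour deviation
    from the target (oscillation amplitude), and biological curves when a
    cell line is available.
    """
    m = results.model
    d = m.dose(results.weights)
    tm = m.regions.tumour_mask(m.grid)
    om = m.regions.oar_mask(m.grid)
    report = {
        "weights": results.weights,
        "cost": results.cost,
        "relative_error": results.relative_error,
        "tumour_dose_min": float(d[tm].min()),
        "tumour_dose_mean": float(d[tm].mean()),
        "tumour_dose_max": float(d[tm].max()),
        "oar_dose_mean": float(d[om].mean()) if om.any() else None,
        "tumour_max_target_deviation": float(
            np.abs(d[tm] - m.target[tm]).max()),
    }
    cell = cell or m.cell
    if cell is not None:
        let = m.dose_let(results.weights)
        bd = d * (1.0 + cell.lam / cell.c_xray * let)
        report["tumour_bd_mean"] = float(bd[tm].mean())
        report["tumour_bd_max"] = float(bd[tm].max())
    return report
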