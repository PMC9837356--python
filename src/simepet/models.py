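"""Model/Results classes for 2TCM and SIME fitting.

Two estimators are provided, both organised as model objects built from data
whose ``fit()`` returns a results object:

:class:`TwoTissueModel`
    Weighted nonlinear least-squares fit of the two-tissue compartment model
    to a single regional TAC, over (K1, k2, k3, k4) with a fixed fractional
    blood volume.  Also supports the constrained refit in which V_ND is fixed
    and K1 = k2 * V_ND.

:class:`SIMEModel`
    Simultaneous estimation across regions: all regional TACs are fitted
    jointly with per-region (k2, k3, k4) plus a single shared V_ND, the
    coupling being K1_r = k2_r * V_ND.  Sharing V_ND removes one parameter
    per region and makes BP_ND = (V_T - V_ND)/V_ND insensitive to scaling
    errors in the input function.  Three fitting routes are available:
    a bounded trust-region least-squares optimizer (default), a bounded
    Nelder-Mead simplex (the historical approach), and a profile grid search
    over V_ND candidates (the independent reference method).

Defaults follow published TSPO-tracer magnitudes: bounds
k2, k3, k4 in [1e-6, 2] min^-1, V_ND in [0.1, 10] ml/cm^3; initial values
k2=0.1, k3=0.05, k4=0.03 min^-1, V_ND=2.0 ml/cm^3.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .blood import InputFunction
from .exceptions import DegenerateFitError, InvalidParameterError
from .frames import FrameSchedule, TimeActivityCurve
from .kinetics import (
    DistributionVolumes,
    RateConstants,
    biexp_irf,
    derive_dvs,
    _check_grid,
    _frame_average,
    _tissue_response,
)

__all__ = [
    "TwoTissueModel",
    "TwoTissueResults",
    "SIMEModel",
    "SIMEResults",
    "SubsetAnalysis",
    "fit_2tcm",
    "sime_joint_fit",
    "sime_grid_search",
    "refit_fixed_vnd",
    "roi_subset_vnd",
    "truncate_tac",
    "BOUNDS",
    "INIT",
]

# parameter bounds and literature-scale initial values
BOUNDS = {
    "K1": (1e-6, 20.0),
    "k2": (1e-6, 2.0),
    "k3": (1e-6, 2.0),
    "k4": (1e-6, 2.0),
    "V_ND": (0.1, 10.0),
}
INIT = {"K1": 0.2, "k2": 0.1, "k3": 0.05, "k4": 0.03, "V_ND": 2.0}

_FTOL = 1e-12
_XTOL = 1e-12
_MAX_NFEV = 5000
_BOUND_ATOL = 1e-8
_BOUND_RTOL = 1e-5


def _resolve_weights(weights, schedule: FrameSchedule) -> np.ndarray:
    """Map a weights specification to per-frame weights.

    ``"frame_duration"`` (2TCM default) weights each frame by its duration,
    normalized to sum to one; ``"uniform"`` and ``None`` give unweighted
    frames; an array is used verbatim.
    """
    if weights is None or weights == "uniform":
        return np.ones(schedule.n_frames)
    if isinstance(weights, str):
        if weights == "frame_duration":
            w = schedule.duration_s.astype(float)
            return w / w.sum() * schedule.n_frames  # keep cost magnitude comparable
        raise InvalidParameterError(f"unknown weights mode {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (schedule.n_frames,) or (w < 0).any():
        raise InvalidParameterError("weights must be per-frame and >= 0")
    return w


def _near_bounds(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> bool:
    tol = _BOUND_ATOL + _BOUND_RTOL * np.abs(np.stack([lo, hi]))
    return bool(((x - lo) <= tol[0]).any() or ((hi - x) <= tol[1]).any())


@dataclass(frozen=True)
class TwoTissueResults:
    """Results of a single-region 2TCM fit."""

    rates: RateConstants
    dvs: DistributionVolumes
    cost: float
    converged: bool
    n_iter: int
    at_bounds: bool
    region: str = ""

    def summary(self) -> pd.DataFrame:
        d, r = self.dvs, self.rates
        return pd.DataFrame(
            {
                "value": [r.K1, r.k2, r.k3, r.k4, d.V_ND, d.V_T, d.V_S, d.BP_ND,
                          self.cost, float(self.converged), float(self.at_bounds)],
            },
            index=["K1", "k2", "k3", "k4", "V_ND", "V_T", "V_S", "BP_ND",
                   "cost", "converged", "at_bounds"],
        )


class _TacFitEngine:
    """Shared machinery: fast residuals of frame-averaged model TACs.

    Precomputes everything that does not depend on the kinetic parameters
    (input interpolation grid, blood-volume term, frame-average operator
    inputs) so each cost evaluation is two IIR filters plus a cumulative sum.
    """

    def __init__(
        self,
        tacs: Sequence[TimeActivityCurve],
        input_function: InputFunction,
        vb: float,
        weights_list: Sequence[np.ndarray],
        frame_stat: str = "mean",
    ):
        if not tacs:
            raise InvalidParameterError("no TACs supplied")
        self.schedule = tacs[0].schedule
        for tac in tacs[1:]:
            if (
                tac.schedule.n_frames != self.schedule.n_frames
                or not np.allclose(tac.schedule.frame_start, self.schedule.frame_start)
                or not np.allclose(tac.schedule.frame_end, self.schedule.frame_end)
            ):
                raise InvalidParameterError("all TACs must share one frame schedule")
        self.tacs = list(tacs)
        self.inp = input_function
        self.dt = _check_grid(input_function)
        if input_function.t_end < self.schedule.total_end_min - 1e-9:
            raise InvalidParameterError(
                "input-function grid does not span the frame schedule"
            )
        self.cp = input_function.require_parent()
        self.vb = float(vb)
        self.blood_term = [
            vb * _frame_average(input_function.time, input_function.whole_blood,
                                self.schedule, frame_stat)
        ][0]
        self.frame_stat = frame_stat
        self.sqrtw = [np.sqrt(w) for w in weights_list]

    def model_frames(self, rates: RateConstants) -> np.ndarray:
        irf = biexp_irf(rates)
        ct = _tissue_response(irf, self.cp, self.dt)
        tissue = _frame_average(self.inp.time, ct, self.schedule, self.frame_stat)
        return (1.0 - self.vb) * tissue + self.blood_term

    def residual_region(self, i: int, rates: RateConstants) -> np.ndarray:
        return self.sqrtw[i] * (self.model_frames(rates) - self.tacs[i].activity)


def _multistart(residual, x0, lo, hi, n_starts, seed):
    """Bounded least squares from the nominal start plus seeded perturbations."""
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, float)
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    solutions = []
    for i in range(n_starts):
        start = x0 if i == 0 else np.clip(x0 * rng.lognormal(0, 0.4, x0.size), lo, hi)
        try:
            sol = optimize.least_squares(
                residual, start, bounds=(lo, hi), method="trf",
                ftol=_FTOL, xtol=_XTOL, gtol=None, max_nfev=_MAX_NFEV,
                x_scale=np.maximum(np.abs(x0), 1e-3),
            )
        except Exception:
            continue
        solutions.append(sol)
    if not solutions:
        return None
    # lowest cost wins; among near-ties prefer the smaller leading parameter
    return min(solutions, key=lambda s: (s.cost, s.x[0]))


class TwoTissueModel:
    """Weighted NLLS fit of the 2TCM to one regional TAC.

    Parameters
    ----------
    tac : TimeActivityCurve
        Frame-averaged regional activity.
    input_function : InputFunction
        Metabolite-corrected plasma-parent + whole-blood curves on a fine
        uniform grid spanning the TAC's schedule.
    weights : "frame_duration" | "uniform" | array | None
        Per-frame fit weights; frames are duration-weighted by default.
    vb : float
        Fractional blood volume, fixed during fitting (default 0.05).
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        input_function: InputFunction,
        weights="frame_duration",
        vb: float = 0.05,
        frame_stat: str = "mean",
    ):
        self.tac = tac
        self.weights = _resolve_weights(weights, tac.schedule)
        if not np.any(tac.activity != 0):
            raise DegenerateFitError(f"TAC {tac.region!r} is identically zero")
        self.engine = _TacFitEngine([tac], input_function, vb, [self.weights], frame_stat)
        self.vb = float(vb)

    def fit(
        self,
        n_starts: int = 3,
        seed: int = 0,
        fix_vnd: float | None = None,
    ) -> TwoTissueResults:
        """Fit (K1, k2, k3, k4); with ``fix_vnd`` fit (k2, k3, k4), K1 = k2*V_ND."""
        eng = self.engine
        if fix_vnd is not None:
            if fix_vnd <= 0:
                raise InvalidParameterError("fixed V_ND must be > 0")

            def residual(p):
                k2, k3, k4 = p
                return eng.residual_region(
                    0, RateConstants(k2 * fix_vnd, k2, k3, k4, self.vb)
                )

            names = ("k2", "k3", "k4")
        else:

            def residual(p):
                return eng.residual_region(0, RateConstants(*p, vB=self.vb))

            names = ("K1", "k2", "k3", "k4")

        lo = np.array([BOUNDS[n][0] for n in names])
        hi = np.array([BOUNDS[n][1] for n in names])
        x0 = np.array([INIT[n] for n in names])
        sol = _multistart(residual, x0, lo, hi, n_starts, seed)
        if sol is None:
            raise DegenerateFitError("2TCM fit failed from every start")
        if fix_vnd is not None:
            k2, k3, k4 = sol.x
            rates = RateConstants(k2 * fix_vnd, k2, k3, k4, self.vb)
        else:
            rates = RateConstants(*sol.x, vB=self.vb)
        return TwoTissueResults(
            rates=rates,
            dvs=derive_dvs(rates),
            cost=float(2.0 * sol.cost),  # least_squares cost is 0.5*sum(r^2)
            converged=bool(sol.status > 0),
            n_iter=int(sol.nfev),
            at_bounds=_near_bounds(sol.x, lo, hi),
            region=self.tac.region,
        )


@dataclass
class SIMEResults:
    """Results of a simultaneous-estimation fit.

    ``per_region`` maps region name to a :class:`TwoTissueResults` whose
    V_ND equals ``V_ND_common`` and whose K1 = k2 * V_ND_common by
    construction.
    """

    V_ND_common: float
    per_region: dict[str, TwoTissueResults]
    total_cost: float
    converged: bool
    failed: bool
    reason: str = ""
    method: str = "optimizer"
    n_starts: int = 0
    grid: np.ndarray | None = field(default=None, repr=False)
    grid_cost: np.ndarray | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for region, res in self.per_region.items():
            r, d = res.rates, res.dvs
            rows[region] = {
                "K1": r.K1, "k2": r.k2, "k3": r.k3, "k4": r.k4,
                "V_ND": d.V_ND, "V_T": d.V_T, "V_S": d.V_S, "BP_ND": d.BP_ND,
                "cost": res.cost, "converged": res.converged,
                "at_bounds": res.at_bounds,
            }
        return pd.DataFrame(rows).T.rename_axis("region")

    def summary(self) -> str:
        lines = [
            "Simultaneous estimation (shared V_ND) results",
            "=" * 46,
            f"method:     {self.method}",
            f"V_ND:       {self.V_ND_common:.4f} ml/cm^3",
            f"total cost: {self.total_cost:.6g}",
            f"converged:  {self.converged}   failed: {self.failed}"
            + (f"   ({self.reason})" if self.reason else ""),
            "",
            self.to_frame().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class SIMEModel:
    """Joint multi-region 2TCM fit with a shared non-displaceable volume.

    The cost is the plain (optionally weighted) sum of squared differences
    between every regional TAC and its model curve, minimized over the
    per-region rates {k2_r, k3_r, k4_r} plus the common V_ND, with
    K1_r = k2_r * V_ND.

    Fewer than 4 regions is accepted but warned about: with 3 regions the
    shared volume is weakly identified and the joint fit is prone to failure.
    """

    def __init__(
        self,
        tacs: Sequence[TimeActivityCurve],
        input_function: InputFunction,
        vb: float = 0.05,
        weights=None,
        frame_stat: str = "mean",
    ):
        if len(tacs) < 4:
            warnings.warn(
                f"SIME with {len(tacs)} region(s): shared V_ND is weakly "
                "identified below 4 regions and the fit may fail",
                stacklevel=2,
            )
        wlist = [_resolve_weights(weights, tacs[0].schedule) for _ in tacs]
        self.engine = _TacFitEngine(list(tacs), input_function, vb, wlist, frame_stat)
        self.tacs = list(tacs)
        self.vb = float(vb)
        self.input_function = input_function

    # -- residual assembly ---------------------------------------------------

    def _rates(self, vnd: float, k: np.ndarray, r: int) -> RateConstants:
        k2, k3, k4 = k[3 * r : 3 * r + 3]
        return RateConstants(k2 * vnd, k2, k3, k4, self.vb)

    def _joint_residual(self, x: np.ndarray) -> np.ndarray:
        vnd, k = x[0], x[1:]
        return np.concatenate(
            [
                self.engine.residual_region(r, self._rates(vnd, k, r))
                for r in range(len(self.tacs))
            ]
        )

    def _pack_results(
        self, vnd: float, k: np.ndarray, converged: bool, method: str, **extra
    ) -> SIMEResults:
        per_region: dict[str, TwoTissueResults] = {}
        total = 0.0
        lo3 = np.array([BOUNDS[n][0] for n in ("k2", "k3", "k4")])
        hi3 = np.array([BOUNDS[n][1] for n in ("k2", "k3", "k4")])
        for r, tac in enumerate(self.tacs):
            rates = self._rates(vnd, k, r)
            resid = self.engine.residual_region(r, rates)
            cost = float(resid @ resid)
            total += cost
            per_region[tac.region] = TwoTissueResults(
                rates=rates,
                dvs=derive_dvs(rates),
                cost=cost,
                converged=converged,
                n_iter=extra.get("n_iter", 0),
                at_bounds=_near_bounds(k[3 * r : 3 * r + 3], lo3, hi3),
                region=tac.region,
            )
        n_at_bounds = sum(res.at_bounds for res in per_region.values())
        failed = (not converged) or (n_at_bounds > len(self.tacs) / 2)
        reason = ""
        if not converged:
            reason = "no start converged"
        elif failed:
            reason = f"{n_at_bounds}/{len(self.tacs)} regional fits at bounds"
        return SIMEResults(
            V_ND_common=float(vnd),
            per_region=per_region,
            total_cost=total,
            converged=converged,
            failed=failed,
            reason=reason,
            method=method,
            n_starts=extra.get("n_starts", 0),
            grid=extra.get("grid"),
            grid_cost=extra.get("grid_cost"),
            meta={"vb": self.vb, "n_regions": len(self.tacs)},
        )

    # -- fitting routes ------------------------------------------------------

    def fit(self, method: str = "optimizer", **kwargs) -> SIMEResults:
        """Estimate the shared V_ND and per-region rates.

        method : "optimizer" (bounded trust-region least squares, default),
        "simplex" (bounded Nelder-Mead on the same cost), or "grid"
        (profile search over V_ND candidates; pass ``grid=``).
        """
        if method == "optimizer":
            return self._fit_optimizer(**kwargs)
        if method == "simplex":
            return self._fit_simplex(**kwargs)
        if method == "grid":
            return self._fit_grid(**kwargs)
        raise InvalidParameterError(f"unknown SIME method {method!r}")

    def _x0_bounds(self):
        nr = len(self.tacs)
        x0 = np.array([INIT["V_ND"]] + [INIT["k2"], INIT["k3"], INIT["k4"]] * nr)
        lo = np.array([BOUNDS["V_ND"][0]] + [BOUNDS[n][0] for n in ("k2", "k3", "k4")] * nr)
        hi = np.array([BOUNDS["V_ND"][1]] + [BOUNDS[n][1] for n in ("k2", "k3", "k4")] * nr)
        return x0, lo, hi

    def _fit_optimizer(self, n_starts: int = 3, seed: int = 0) -> SIMEResults:
        x0, lo, hi = self._x0_bounds()
        sol = _multistart(self._joint_residual, x0, lo, hi, n_starts, seed)
        if sol is None:
            return self._pack_results(INIT["V_ND"], x0[1:], False, "optimizer",
                                      n_starts=n_starts)
        return self._pack_results(
            float(sol.x[0]), sol.x[1:], bool(sol.status > 0), "optimizer",
            n_starts=n_starts, n_iter=int(sol.nfev),
        )

    def _fit_simplex(self, n_starts: int = 3, seed: int = 0,
                     max_iter: int = 5000) -> SIMEResults:
        """Bounded Nelder-Mead via a sine transform of the box constraints."""
        x0, lo, hi = self._x0_bounds()

        def to_unbounded(x):
            return np.arcsin(np.clip(2 * (x - lo) / (hi - lo) - 1, -1, 1))

        def to_bounded(u):
            return lo + (np.sin(u) + 1) * (hi - lo) / 2

        def cost(u):
            resid = self._joint_residual(to_bounded(u))
            return float(resid @ resid)

        rng = np.random.default_rng(seed)
        best = None
        for i in range(n_starts):
            start = x0 if i == 0 else np.clip(
                x0 * rng.lognormal(0, 0.4, x0.size), lo, hi)
            sol = optimize.minimize(
                cost, to_unbounded(start), method="Nelder-Mead",
                options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-12},
            )
            if best is None or sol.fun < best.fun:
                best = sol
        x = to_bounded(best.x)
        return self._pack_results(
            float(x[0]), x[1:], bool(best.success), "simplex",
            n_starts=n_starts, n_iter=int(best.nit),
        )

    def _fit_grid(
        self,
        grid: Sequence[float] | None = None,
        seed: int = 0,
        refine: bool = False,
    ) -> SIMEResults:
        """Profile grid search over V_ND (the reference variant).

        For each candidate V_ND the per-region (k2, k3, k4) are fitted with
        K1 = k2 * V_ND; the candidate minimizing the total cost wins.
        Successive candidates warm-start from the previous solution.  With
        ``refine=True`` a parabolic interpolation through the minimum and its
        neighbours sharpens the estimate (off by default).
        """
        if grid is None:
            grid = np.arange(0.5, 6.0 + 1e-9, 0.05)
        grid = np.asarray(list(grid), dtype=float)
        if grid.size == 0 or (grid.size > 1 and not (np.diff(grid) > 0).all()):
            raise InvalidParameterError("grid must be non-empty and increasing")
        eng = self.engine
        nr = len(self.tacs)
        lo = np.array([BOUNDS[n][0] for n in ("k2", "k3", "k4")])
        hi = np.array([BOUNDS[n][1] for n in ("k2", "k3", "k4")])
        x0 = np.array([INIT["k2"], INIT["k3"], INIT["k4"]])

        cost_curve = np.empty(grid.size)
        params = np.empty((grid.size, nr, 3))
        warm = [x0.copy() for _ in range(nr)]
        for gi, vnd in enumerate(grid):
            total = 0.0
            for r in range(nr):

                def residual(p, r=r, vnd=vnd):
                    k2, k3, k4 = p
                    return eng.residual_region(
                        r, RateConstants(k2 * vnd, k2, k3, k4, self.vb)
                    )

                sol = optimize.least_squares(
                    residual, warm[r], bounds=(lo, hi), method="trf",
                    ftol=_FTOL, xtol=_XTOL, gtol=None, max_nfev=_MAX_NFEV,
                    x_scale=np.maximum(np.abs(x0), 1e-3),
                )
                warm[r] = sol.x.copy()
                params[gi, r] = sol.x
                total += 2.0 * sol.cost
            cost_curve[gi] = total

        imin = int(np.argmin(cost_curve))
        if grid.size > 1 and imin in (0, grid.size - 1):
            warnings.warn(
                f"grid-search minimum at endpoint V_ND={grid[imin]:.3g}; "
                "the optimum may lie outside the grid",
                stacklevel=2,
            )
        vnd_hat = float(grid[imin])
        if refine and 0 < imin < grid.size - 1:
            y0, y1, y2 = cost_curve[imin - 1 : imin + 2]
            denom = y0 - 2 * y1 + y2
            if denom > 0:
                vnd_hat = float(
                    grid[imin] + 0.5 * (grid[imin + 1] - grid[imin]) * (y0 - y2) / denom
                )
        res = self._pack_results(
            vnd_hat, params[imin].ravel(), True, "grid",
            grid=grid, grid_cost=cost_curve,
        )
        return res

    # -- companions ----------------------------------------------------------

    def subset_analysis(self, k: int, **fit_kwargs) -> "SubsetAnalysis":
        """Re-run SIME on every k-region subset of this model's regions."""
        nr = len(self.tacs)
        if not (3 <= k <= nr):
            raise InvalidParameterError(f"subset size {k} outside [3, {nr}]")
        if k == 3:
            warnings.warn(
                "subset size 3: SIME is known to fail with only 3 regions",
                stacklevel=2,
            )
        entries = []
        for combo in itertools.combinations(range(nr), k):
            tacs = [self.tacs[i] for i in combo]
            names = tuple(t.region for t in tacs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = SIMEModel(tacs, self.input_function, self.vb)
                try:
                    res = model.fit(**fit_kwargs)
                except Exception as exc:  # per-subset failure is not fatal
                    res = None
                    entries.append((names, res))
                    continue
            entries.append((names, res))
        return SubsetAnalysis(k=k, entries=entries)


@dataclass
class SubsetAnalysis:
    """V_ND across all k-region subsets: per-subset results plus spread."""

    k: int
    entries: list[tuple[tuple[str, ...], SIMEResults | None]]

    @property
    def vnd_values(self) -> np.ndarray:
        return np.array(
            [e.V_ND_common for _, e in self.entries if e is not None and not e.failed]
        )

    @property
    def vnd_mean(self) -> float:
        return float(np.mean(self.vnd_values))

    @property
    def vnd_sd(self) -> float:
        return float(np.std(self.vnd_values, ddof=1)) if self.vnd_values.size > 1 else 0.0

    @property
    def n_failed(self) -> int:
        return sum(1 for _, e in self.entries if e is None or e.failed)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for names, res in self.entries:
            rows.append(
                {
                    "subset": "+".join(names),
                    "V_ND": np.nan if res is None else res.V_ND_common,
                    "failed": res is None or res.failed,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional wrappers (the procedural surface of the fitting layer)


def fit_2tcm(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    weights="frame_duration",
    vb: float = 0.05,
    **fit_kwargs,
) -> TwoTissueResults:
    """Weighted NLLS 2TCM fit of one regional TAC."""
    return TwoTissueModel(tac, input_function, weights=weights, vb=vb).fit(**fit_kwargs)


def sime_joint_fit(
    tacs: Sequence[TimeActivityCurve],
    input_function: InputFunction,
    vb: float = 0.05,
    weights=None,
    **fit_kwargs,
) -> SIMEResults:
    """Simultaneous estimation of per-region rates and a common V_ND."""
    return SIMEModel(tacs, input_function, vb=vb, weights=weights).fit(
        method="optimizer", **fit_kwargs
    )


def sime_grid_search(
    tacs: Sequence[TimeActivityCurve],
    input_function: InputFunction,
    grid: Sequence[float] | None = None,
    vb: float = 0.05,
    weights=None,
    **fit_kwargs,
) -> SIMEResults:
    """Profile grid-search SIME over V_ND candidates (reference variant)."""
    return SIMEModel(tacs, input_function, vb=vb, weights=weights).fit(
        method="grid", grid=grid, **fit_kwargs
    )


def refit_fixed_vnd(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    V_ND: float,
    vb: float = 0.05,
    weights="frame_duration",
    **fit_kwargs,
) -> TwoTissueResults:
    """Single-region refit with V_ND fixed (K1 = k2 * V_ND)."""
    if V_ND <= 0:
        raise InvalidParameterError(f"V_ND must be > 0, got {V_ND}")
    return TwoTissueModel(tac, input_function, weights=weights, vb=vb).fit(
        fix_vnd=V_ND, **fit_kwargs
    )


def roi_subset_vnd(
    tacs: Sequence[TimeActivityCurve],
    input_function: InputFunction,
    k: int,
    vb: float = 0.05,
    **fit_kwargs,
) -> SubsetAnalysis:
    """SIME V_ND across every k-region subset of the supplied regions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SIMEModel(tacs, input_function, vb=vb)
    return model.subset_analysis(k, **fit_kwargs)


def truncate_tac(tac: TimeActivityCurve, duration_min: float) -> TimeActivityCurve:
    """Drop frames ending after ``duration_min``; warn if nothing is dropped
    because the scan is already shorter than the requested duration."""
    if duration_min > tac.schedule.total_end_min:
        warnings.warn(
            f"truncation at {duration_min} min exceeds the scan end "
            f"({tac.schedule.total_end_min:.1f} min); TAC unchanged",
            stacklevel=2,
        )
        return tac
    return tac.truncated(duration_min)
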