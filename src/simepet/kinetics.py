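"""Two-tissue compartment model (2TCM) forward kinetics.

The 2TCM describes tracer exchange between plasma and two tissue
compartments (free/non-specific, and specifically bound) with rate constants
K1 [ml·cm^-3·min^-1] and k2, k3, k4 [min^-1].  Its impulse response to a
unit plasma input is the biexponential

    IRF(t) = phi1 * exp(-theta1 t) + phi2 * exp(-theta2 t),

with theta_{1,2} = ((k2+k3+k4) ± sqrt((k2+k3+k4)^2 - 4 k2 k4)) / 2 and
amplitudes phi1 = K1 (theta1 - k3 - k4)/(theta1 - theta2),
phi2 = K1 (k3 + k4 - theta2)/(theta1 - theta2).  The measured PET signal in
a region also contains a fractional blood-volume contribution vB:

    C_model(t) = (1 - vB) * (Cp_parent (*) IRF)(t) + vB * Cwb(t),

and scanners report the time-average of C_model over each frame.

Macro-parameters follow from the rates: the non-displaceable distribution
volume V_ND = K1/k2, the total distribution volume V_T = V_ND (1 + k3/k4),
the specific distribution volume V_S = V_T - V_ND, and the binding potential
BP_ND = V_S / V_ND.

Convolution is evaluated on the input function's uniform fine grid with the
input treated as piecewise linear; the convolution with each exponential is
then an exact first-order recursion, run at C speed via ``scipy.signal.lfilter``.
All times are minutes internally; activities are kBq/ml and assumed
decay-corrected (no decay term appears in the model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .blood import InputFunction
from .exceptions import CoverageError, InvalidParameterError, UnboundedVTError
from .frames import FrameSchedule, TimeActivityCurve

__all__ = [
    "RateConstants",
    "BiexpIRF",
    "DistributionVolumes",
    "biexp_irf",
    "derive_dvs",
    "model_tac",
]

#: discriminant tolerance below which the two IRF rates are treated as equal
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class RateConstants:
    """2TCM micro-parameters plus the fractional blood volume vB."""

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.05

    def __post_init__(self) -> None:
        vals = (self.K1, self.k2, self.k3, self.k4, self.vB)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("rate constants must be finite")
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise InvalidParameterError("rate constants must be >= 0")
        if not (0.0 <= self.vB < 1.0):
            raise InvalidParameterError(f"vB = {self.vB} outside [0, 1)")

    @classmethod
    def from_volumes(
        cls,
        V_ND: float,
        V_T: float,
        k2: float = 0.1,
        k4: float = 0.047,
        vB: float = 0.05,
    ) -> "RateConstants":
        """Back-construct rates from target distribution volumes.

        K1 = k2 * V_ND and k3 = k4 * (V_T/V_ND - 1); k2 and k4 are free
        (the macro-parameters do not pin them down) and default to values
        of the magnitude reported for TSPO tracers.
        """
        if V_ND <= 0 or V_T < V_ND:
            raise InvalidParameterError("need V_ND > 0 and V_T >= V_ND")
        return cls(K1=k2 * V_ND, k2=k2, k3=k4 * (V_T / V_ND - 1.0), k4=k4, vB=vB)

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4])


@dataclass(frozen=True)
class BiexpIRF:
    """Analytic 2TCM impulse response.

    When the characteristic discriminant vanishes (theta1 == theta2 == theta)
    the response degenerates to ``K1 e^{-theta t} (1 + (theta - k3 - k4) t)``;
    ``degenerate`` flags that branch and ``slope_amp`` carries the t-term
    amplitude K1 (theta - k3 - k4).
    """

    phi1: float
    phi2: float
    theta1: float
    theta2: float
    degenerate: bool = False
    slope_amp: float = 0.0

    @property
    def K1(self) -> float:
        return self.phi1 + self.phi2

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.degenerate:
            return (self.K1 + self.slope_amp * t) * np.exp(-self.theta1 * t)
        return self.phi1 * np.exp(-self.theta1 * t) + self.phi2 * np.exp(-self.theta2 * t)

    def integral(self) -> float:
        """Total integral of the IRF — equal to V_T when it is finite."""
        if self.degenerate:
            if self.theta1 == 0:
                return np.inf if (self.K1 > 0 or self.slope_amp > 0) else 0.0
            return self.K1 / self.theta1 + self.slope_amp / self.theta1**2
        total = 0.0
        for phi, theta in ((self.phi1, self.theta1), (self.phi2, self.theta2)):
            if phi == 0.0:
                continue
            if theta == 0.0:
                return np.inf
            total += phi / theta
        return total


@dataclass(frozen=True)
class DistributionVolumes:
    """Macro-parameters of the 2TCM (ml/cm^3, BP_ND unitless)."""

    V_ND: float
    V_T: float
    V_S: float
    BP_ND: float

    def __post_init__(self) -> None:
        if min(self.V_ND, self.V_T, self.V_S, self.BP_ND) < 0:
            raise InvalidParameterError("distribution volumes must be >= 0")


def biexp_irf(rates: RateConstants) -> BiexpIRF:
    """Closed-form impulse response of the 2TCM."""
    K1, k2, k3, k4 = rates.K1, rates.k2, rates.k3, rates.k4
    if k2 <= 0:
        raise InvalidParameterError("biexp_irf requires k2 > 0")
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < _DEGENERATE_TOL * max(s * s, 1.0):
        theta = 0.5 * s
        return BiexpIRF(
            phi1=K1, phi2=0.0, theta1=theta, theta2=theta,
            degenerate=True, slope_amp=K1 * (theta - k3 - k4),
        )
    root = np.sqrt(disc)
    theta1 = 0.5 * (s + root)
    theta2 = 0.5 * (s - root)
    phi1 = K1 * (theta1 - k3 - k4) / root
    phi2 = K1 * (k3 + k4 - theta2) / root
    return BiexpIRF(phi1=phi1, phi2=phi2, theta1=theta1, theta2=theta2)


def derive_dvs(rates: RateConstants) -> DistributionVolumes:
    """Distribution volumes and binding potential from the rate constants."""
    if rates.k2 <= 0:
        raise InvalidParameterError("V_ND = K1/k2 requires k2 > 0")
    V_ND = rates.K1 / rates.k2
    if rates.k3 == 0:
        V_T = V_ND
    elif rates.k4 <= 0:
        raise UnboundedVTError("k4 = 0 with k3 > 0: V_T is unbounded")
    else:
        V_T = V_ND * (1.0 + rates.k3 / rates.k4)
    V_S = V_T - V_ND
    BP_ND = V_S / V_ND if V_ND > 0 else 0.0
    return DistributionVolumes(V_ND=V_ND, V_T=V_T, V_S=V_S, BP_ND=BP_ND)


def _exp_conv(x: np.ndarray, dt: float, theta: float) -> np.ndarray:
    """Continuous convolution of a piecewise-linear signal with exp(-theta t).

    Exact for piecewise-linear ``x`` on a uniform grid of spacing ``dt``:
    y_i = E y_{i-1} + a0 x_i + a1 x_{i-1} with E = exp(-theta dt) and
    trapezoid-free analytic step integrals I0 = (1-E)/theta,
    I1 = (1-(1+theta dt)E)/theta^2; a0 = I0 - I1/dt, a1 = I1/dt.
    """
    td = theta * dt
    if td < 1e-8:  # series limit, stable as theta -> 0
        I0 = dt * (1.0 - 0.5 * td)
        I1 = 0.5 * dt * dt * (1.0 - 2.0 * td / 3.0)
        E = np.exp(-td)
    else:
        E = np.exp(-td)
        I0 = -np.expm1(-td) / theta
        I1 = (1.0 - (1.0 + td) * E) / (theta * theta)
    a0 = I0 - I1 / dt
    a1 = I1 / dt
    forcing = a0 * x[1:] + a1 * x[:-1]
    y = np.empty_like(x)
    y[0] = 0.0
    y[1:] = lfilter([1.0], [1.0, -E], forcing)
    return y


def _tissue_response(irf: BiexpIRF, cp: np.ndarray, dt: float) -> np.ndarray:
    """Tissue concentration (Cp (*) IRF) on the uniform grid."""
    if irf.degenerate:
        base = _exp_conv(cp, dt, irf.theta1)
        # t*exp(-theta t) = exp(-theta t) (*) exp(-theta t)
        return irf.K1 * base + irf.slope_amp * _exp_conv(base, dt, irf.theta1)
    return irf.phi1 * _exp_conv(cp, dt, irf.theta1) + irf.phi2 * _exp_conv(
        cp, dt, irf.theta2
    )


def _check_grid(inp: InputFunction) -> float:
    dts = np.diff(inp.time)
    dt = float(dts[0])
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-12):
        raise InvalidParameterError("input-function grid must be uniform")
    return dt


def _frame_average(
    t: np.ndarray, c: np.ndarray, schedule: FrameSchedule, stat: str
) -> np.ndarray:
    if stat == "midpoint":
        return np.interp(schedule.mid_min, t, c)
    if stat != "mean":
        raise InvalidParameterError(f"unknown frame statistic {stat!r}")
    dt = t[1] - t[0]
    # cumulative trapezoid integral; exact at grid nodes for linear segments
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * dt)])
    lo = np.interp(schedule.start_min, t, cum)
    hi = np.interp(schedule.end_min, t, cum)
    return (hi - lo) / (schedule.end_min - schedule.start_min)


def model_tac(
    rates: RateConstants,
    input_function: InputFunction,
    schedule: FrameSchedule,
    frame_stat: str = "mean",
    region: str = "model",
) -> TimeActivityCurve:
    """Forward-model a regional TAC from rates, input function and schedule.

    ``C_model(t) = (1-vB) * (Cp_parent (*) IRF)(t) + vB * Cwb(t)``, reported
    per frame either as the time-average over the frame (default — how
    scanners report frames) or sampled at the frame midpoint.
    """
    dt = _check_grid(input_function)
    if input_function.time[0] > 1e-9 or input_function.t_end < schedule.total_end_min - 1e-9:
        raise CoverageError(
            f"input grid [{input_function.time[0]:.2f}, {input_function.t_end:.2f}] min "
            f"does not span the schedule (needs [0, {schedule.total_end_min:.2f}] min)"
        )
    cp = input_function.require_parent()
    irf = biexp_irf(rates)
    c_model = (1.0 - rates.vB) * _tissue_response(irf, cp, dt) + (
        rates.vB * input_function.whole_blood
    )
    activity = _frame_average(input_function.time, c_model, schedule, frame_stat)
    return TimeActivityCurve(region=region, schedule=schedule, activity=activity)
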