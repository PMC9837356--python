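"""Blood-sample models and input-function construction.

Compartmental quantification needs the concentration of *unmetabolized parent
tracer in plasma*, while what is measured (by a well counter, or from a
carotid image) is whole-blood activity.  Two empirical correction models
bridge the gap:

* the blood-to-plasma ratio BPR(t), fitted with a biexponential
  ``A1*exp(-lam1*t) + A2*exp(-lam2*t)``;
* the parent fraction f(t) — the fraction of plasma activity coming from
  unmetabolized tracer — fitted with a Hill-type function
  ``f(t) = 1 - (1-a)*t**b / (c + t**b)`` so that f(0)=1 and f(inf)=a.

The metabolite-corrected plasma-parent input is then
``Cp(t) = Cwb(t) / BPR(t) * f(t)``.

Image-derived input functions (IDIFs) are known only up to a scale factor;
:func:`scale_idif` anchors them to late venous whole-blood samples (default
45/60/90 min, when arterial and venous concentrations have equilibrated).
:func:`venous_arterial_agreement` implements the paired regression comparison
used to validate venous against arterial metabolite measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    DegenerateRegressionError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidSampleError,
    ModelDomainError,
    ScalingError,
)

__all__ = [
    "BloodSample",
    "BPRModel",
    "HillModel",
    "InputFunction",
    "AgreementStats",
    "fit_bpr",
    "fit_parent_fraction",
    "metabolite_correct",
    "scale_idif",
    "venous_arterial_agreement",
]


@dataclass(frozen=True)
class BloodSample:
    """One manual blood draw.

    ``time`` is minutes post-injection; activities are kBq/ml.
    ``parent_fraction`` (fraction of plasma activity from unmetabolized
    tracer, in [0, 1]) is optional — not every draw is analysed by
    chromatography.
    """

    time: float
    whole_blood: float
    plasma: float
    parent_fraction: float | None = None
    site: Literal["arterial", "venous"] = "venous"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidSampleError(f"sample time {self.time} < 0")
        if self.whole_blood < 0 or self.plasma < 0:
            raise InvalidSampleError("blood activities must be >= 0")
        if self.parent_fraction is not None and not (0.0 <= self.parent_fraction <= 1.0):
            raise InvalidSampleError(
                f"parent_fraction {self.parent_fraction} outside [0, 1]"
            )
        if self.site not in ("arterial", "venous"):
            raise InvalidSampleError(f"unknown sampling site {self.site!r}")


@dataclass(frozen=True)
class BPRModel:
    """Biexponential blood-to-plasma ratio, ``A1*e^(-lam1 t) + A2*e^(-lam2 t)``.

    Amplitudes and rates are non-negative and the decay rates are ordered
    ``lam1 >= lam2``; a plateau is expressed by ``lam2 -> 0``.
    """

    A1: float
    A2: float
    lam1: float
    lam2: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if min(self.A1, self.A2, self.lam1, self.lam2) < 0:
            raise InvalidParameterError("BPR amplitudes and rates must be >= 0")
        if self.lam1 < self.lam2:
            raise InvalidParameterError("BPR rates must satisfy lam1 >= lam2")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.A1 * np.exp(-self.lam1 * t) + self.A2 * np.exp(-self.lam2 * t)


@dataclass(frozen=True)
class HillModel:
    """Hill-type parent-fraction curve ``f(t) = 1 - (1-a) t^b / (c + t^b)``.

    ``a`` is the late-time plateau fraction, ``b`` the Hill slope and ``c``
    a half-saturation scale (units min^b).  By construction f(0) = 1, f is
    monotone non-increasing, and f(inf) = a.
    """

    a: float
    b: float
    c: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise InvalidParameterError(f"plateau a={self.a} outside [0, 1]")
        if self.b <= 0 or self.c <= 0:
            raise InvalidParameterError("Hill slope b and scale c must be > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tb = np.power(np.maximum(t, 0.0), self.b)
        return 1.0 - (1.0 - self.a) * tb / (self.c + tb)


@dataclass(frozen=True)
class InputFunction:
    """Whole-blood and plasma-parent concentration on a fine uniform grid.

    ``time`` is minutes; activities kBq/ml.  ``plasma_parent`` may be absent
    (e.g. a raw whole-blood IDIF before metabolite correction).
    """

    time: np.ndarray = field(repr=False)
    whole_blood: np.ndarray = field(repr=False)
    plasma_parent: np.ndarray | None = field(default=None, repr=False)
    provenance: Literal["AIF", "IDIF", "synthetic"] = "AIF"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        wb = np.asarray(self.whole_blood, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "whole_blood", wb)
        if t.ndim != 1 or t.size < 2:
            raise InvalidParameterError("time grid must be 1-D with >= 2 points")
        if not (np.diff(t) > 0).all():
            raise InvalidParameterError("time grid must be strictly increasing")
        if wb.shape != t.shape:
            raise InvalidParameterError("whole_blood must match the time grid")
        if self.plasma_parent is not None:
            pp = np.asarray(self.plasma_parent, dtype=float)
            object.__setattr__(self, "plasma_parent", pp)
            if pp.shape != t.shape:
                raise InvalidParameterError("plasma_parent must match the time grid")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def t_end(self) -> float:
        return float(self.time[-1])

    def require_parent(self) -> np.ndarray:
        if self.plasma_parent is None:
            raise InvalidParameterError(
                "input function has no plasma_parent curve; run metabolite_correct first"
            )
        return self.plasma_parent

    def scaled(self, s: float) -> "InputFunction":
        """Multiply both curves by a scalar (used by IDIF scaling and tests)."""
        pp = None if self.plasma_parent is None else s * self.plasma_parent
        return replace(self, whole_blood=s * self.whole_blood, plasma_parent=pp)

    def scaled_parent(self, s: float) -> "InputFunction":
        """Multiply only the plasma-parent curve by a scalar.

        Emulates a pure scaling error in the metabolite-corrected AIF (the
        curve that drives the tissue model); the whole-blood curve feeding
        the fixed blood-volume term is left untouched.  Under such an error
        fitted K1, V_ND and V_T scale exactly by 1/s while BP_ND is
        invariant.
        """
        return replace(self, plasma_parent=s * self.require_parent())

    def wb_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.time, self.whole_blood)


@dataclass(frozen=True)
class AgreementStats:
    """Venous-vs-arterial agreement: OLS of venous (y) on arterial (x)."""

    r_squared: float
    slope: float
    intercept: float
    p_slope_vs_one: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidParameterError("r_squared outside [0, 1]")


# ---------------------------------------------------------------------------
# fitting helpers

_N_STARTS = 3
_START_SEED = 20230112  # fixed: fits must be reproducible run-to-run


def _multistart_ls(residual, x0, bounds, n_starts=_N_STARTS):
    """Bounded least squares from several fixed-seed perturbed starts.

    Returns the solution with the lowest cost; guards against the local
    minima that plague sums of exponentials.
    """
    rng = np.random.default_rng(_START_SEED)
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    best = None
    for i in range(n_starts):
        if i == 0:
            start = np.asarray(x0, float)
        else:
            start = np.asarray(x0, float) * rng.lognormal(0.0, 0.5, size=len(x0))
        start = np.clip(start, lo, np.where(np.isfinite(hi), hi, start))
        try:
            sol = optimize.least_squares(
                residual, start, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=5000,
            )
        except Exception:  # singular jacobian from a pathological start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise InsufficientDataError("least-squares fit failed from every start")
    return best


def fit_bpr(samples: Sequence[BloodSample]) -> BPRModel:
    """Fit the biexponential blood-to-plasma ratio to paired activities.

    BPR points are formed as ``whole_blood / plasma`` per sample; at least 4
    samples with plasma > 0 are required.  Amplitudes and rates are bounded
    below by zero, so a flat ratio is represented by both rates collapsing
    to ~0.
    """
    usable = [s for s in samples if s.plasma is not None]
    for s in usable:
        if s.plasma == 0:
            raise InvalidSampleError(f"sample at t={s.time} min has plasma = 0")
    if len(usable) < 4:
        raise InsufficientDataError(
            f"need >= 4 samples with plasma > 0 to fit a BPR model, got {len(usable)}"
        )
    t = np.array([s.time for s in usable])
    y = np.array([s.whole_blood / s.plasma for s in usable])

    def residual(p):
        A1, A2, l1, l2 = p
        return A1 * np.exp(-l1 * t) + A2 * np.exp(-l2 * t) - y

    ybar = float(np.mean(y))
    x0 = [0.5 * ybar, 0.5 * ybar, 0.1, 1e-3]
    sol = _multistart_ls(residual, x0, ([0, 0, 0, 0], [np.inf, np.inf, 10.0, 10.0]))
    A1, A2, l1, l2 = sol.x
    if l1 < l2:  # enforce the lam1 >= lam2 ordering convention
        A1, A2, l1, l2 = A2, A1, l2, l1
    return BPRModel(A1, A2, l1, l2, rss=float(np.sum(residual([A1, A2, l1, l2]) ** 2)))


def fit_parent_fraction(samples: Sequence[BloodSample]) -> HillModel:
    """Fit the Hill parent-fraction model to measured fractions."""
    usable = [s for s in samples if s.parent_fraction is not None]
    if len(usable) < 4:
        raise InsufficientDataError(
            f"need >= 4 samples with parent_fraction to fit a Hill model, got {len(usable)}"
        )
    t = np.array([s.time for s in usable])
    y = np.array([s.parent_fraction for s in usable])

    def residual(p):
        a, b, c = p
        tb = np.power(np.maximum(t, 0.0), b)
        return 1.0 - (1.0 - a) * tb / (c + tb) - y

    x0 = [max(float(y.min()), 1e-3), 1.5, 50.0]
    sol = _multistart_ls(residual, x0, ([0.0, 1e-3, 1e-6], [1.0, 10.0, 1e6]))
    a, b, c = sol.x
    return HillModel(a, b, c, rss=float(np.sum(residual(sol.x) ** 2)))


def metabolite_correct(
    wb_curve: InputFunction, bpr: BPRModel, hill: HillModel
) -> InputFunction:
    """Build the plasma-parent curve: ``Cp(t) = Cwb(t)/BPR(t) * f(t)``."""
    ratio = bpr(wb_curve.time)
    if (ratio <= 0).any():
        t_bad = wb_curve.time[np.argmax(ratio <= 0)]
        raise ModelDomainError(f"fitted BPR is <= 0 at t = {t_bad:.2f} min")
    parent = wb_curve.whole_blood / ratio * hill(wb_curve.time)
    return replace(wb_curve, plasma_parent=parent)


def scale_idif(
    idif: InputFunction,
    venous: Sequence[BloodSample],
    times: Sequence[float] = (45.0, 60.0, 90.0),
) -> tuple[InputFunction, float]:
    """Scale an IDIF to late venous whole-blood samples.

    The scalar ``s`` minimizes ``sum_i (venous_i - s * idif(t_i))**2``, i.e.
    ``s = sum v_i u_i / sum u_i**2`` with ``u_i = idif(t_i)``.  Returns the
    scaled curve and ``s``.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ScalingError("no scaling times requested")
    if (times > idif.t_end + 1e-9).any() or (times < idif.time[0] - 1e-9).any():
        raise ScalingError(
            f"IDIF support [{idif.time[0]:.1f}, {idif.t_end:.1f}] min does not "
            f"cover the scaling times {times.tolist()}"
        )
    v = []
    for t in times:
        matches = [s for s in venous if s.site == "venous" and abs(s.time - t) < 0.5]
        if not matches:
            raise ScalingError(f"no venous sample at t = {t:g} min")
        v.append(float(np.mean([m.whole_blood for m in matches])))
    v = np.asarray(v)
    u = idif.wb_at(times)
    denom = float(np.sum(u * u))
    if denom == 0.0:
        raise ScalingError("IDIF is zero at every scaling time")
    s = float(np.sum(v * u) / denom)
    return idif.scaled(s), s


def venous_arterial_agreement(
    paired: Sequence[tuple[float, float]]
) -> AgreementStats:
    """OLS regression of venous (response) on arterial (predictor) values.

    Returns Pearson r^2, the regression line, and a two-sided t test of
    slope = 1 (the null of perfect venous/arterial interchangeability).
    For an exact noiseless line the slope standard error is zero; the
    p-value is then 1.0 if the slope equals one and 0.0 otherwise.
    """
    pairs = np.asarray(list(paired), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise InsufficientDataError("need >= 3 (venous, arterial) pairs")
    ven, art = pairs[:, 0], pairs[:, 1]
    if np.ptp(art) == 0:
        raise DegenerateRegressionError("arterial values have zero variance")
    res = stats.linregress(art, ven)
    n = pairs.shape[0]
    if res.stderr == 0.0:
        p = 1.0 if res.slope == 1.0 else 0.0
    else:
        tstat = (res.slope - 1.0) / res.stderr
        p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return AgreementStats(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_slope_vs_one=p,
        n=n,
    )
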