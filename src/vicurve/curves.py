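"""Visual-curve fitting and Area-of-the-Curve (AoC) indices.

The visual curve (ViC) models a patient's visual acuity (Letters) as a
polynomial function of viewing distance. The Area of the Curve is the
analytic integral of that polynomial between the nearest and farthest
tested distances, decomposed into a near-vision part (distances up to
50 cm, AoCN) and a distance-vision part (beyond 50 cm, AoCD). A
piecewise-linear comparator mirrors conventional defocus-curve testing
(DCT): straight lines join the measured points and areas are exact
trapezoid sums.

Polynomial degree is chosen deterministically: with five or fewer points
the curve interpolates exactly (degree = points - 1); with more points the
degree minimising leave-one-out cross-validation RMSE is used, ties broken
toward the lower degree. Fits are performed in a rescaled coordinate
(domain mapped to [-1, 1]) for numerical conditioning and converted back
to raw ascending-degree coefficients over distance in cm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from numpy.polynomial import polynomial as npoly

from .errors import DomainError, InsufficientDataError, PipelineError
from .profiles import ALL_SUBSETS, NEAR_SPLIT_CM, SUBSETS, DistanceSubset, VAProfile


class CurveRangeWarning(UserWarning):
    """The fitted polynomial leaves [0, 100] Letters inside its domain."""


@dataclass(frozen=True)
class VisualCurve:
    """A fitted polynomial visual curve.

    ``coefficients`` are raw ascending-degree coefficients over the x axis
    (distance in cm by default, diopters if ``x_axis == 'diopters'``);
    ``domain`` is the closed fitting interval on that axis.
    """

    coefficients: Tuple[float, ...]
    domain: Tuple[float, float]
    degree: int
    subset_id: str
    residuals: Tuple[float, ...]
    cv_rmse: Optional[float] = None
    x_axis: str = "cm"

    @property
    def exits_va_range(self) -> bool:
        """True if the curve leaves [0, 100] Letters inside its domain."""
        xs = np.linspace(self.domain[0], self.domain[1], 201)
        ys = npoly.polyval(xs, np.asarray(self.coefficients))
        return bool((ys < -1e-9).any() or (ys > 100.0 + 1e-9).any())


@dataclass(frozen=True)
class AoCResult:
    """Total, near (<= 50 cm) and distance (> 50 cm) areas in Letters*cm."""

    total: float
    near: float
    distance: float
    subset_id: str
    method: str  # "polynomial" | "piecewise_linear"


# --------------------------------------------------------------------------
# fitting machinery

def _scale(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return (2.0 * x - (a + b)) / (b - a)


@lru_cache(maxsize=16384)
def _design(x_key: Tuple[float, ...], degree: int, a: float, b: float):
    """Vandermonde design in the scaled coordinate and its pseudo-inverse."""
    t = _scale(np.asarray(x_key), a, b)
    V = np.vander(t, degree + 1, increasing=True)
    return V, np.linalg.pinv(V)


def _lstsq_coef(x: np.ndarray, y: np.ndarray, degree: int, a: float, b: float) -> np.ndarray:
    _, pinv = _design(tuple(x), degree, a, b)
    return pinv @ y


def _loocv_errors(x: np.ndarray, y: np.ndarray, degree: int, a: float, b: float) -> np.ndarray:
    """Leave-one-out prediction errors of a least-squares fit, by refitting."""
    errs = np.empty(len(x))
    for i in range(len(x)):
        xr = np.delete(x, i)
        yr = np.delete(y, i)
        coef = _lstsq_coef(xr, yr, degree, a, b)
        ti = _scale(np.asarray([x[i]]), a, b)
        pred = npoly.polyval(ti, coef)[0]
        errs[i] = y[i] - pred
    return errs


def _loocv_rmse(x: np.ndarray, y: np.ndarray, degree: int, a: float, b: float) -> float:
    return float(np.sqrt(np.mean(_loocv_errors(x, y, degree, a, b) ** 2)))


#: candidate degrees considered by cross-validated selection
CANDIDATE_DEGREES = (3, 4, 5, 6)

#: a candidate fit swinging further than this many Letters beyond the
#: observed VA range is an overfit artefact and excluded from selection;
#: the band is data-relative so that degree selection (and hence AoC) is
#: covariant under constant shifts of the profile
_PLAUSIBLE_MARGIN = 30.0


def _fit_in_range(x: np.ndarray, y: np.ndarray, degree: int, a: float, b: float) -> bool:
    coef = _lstsq_coef(x, y, degree, a, b)
    t = np.linspace(-1.0, 1.0, 101)
    vals = npoly.polyval(t, coef)
    return bool(vals.min() >= y.min() - _PLAUSIBLE_MARGIN
                and vals.max() <= y.max() + _PLAUSIBLE_MARGIN)


def select_degree(points: Sequence[Tuple[float, float]]) -> int:
    """Choose the polynomial degree for a set of (distance, VA) points.

    With k <= 5 points the degree is k - 1 (exact interpolation). With
    more points, degrees from :data:`CANDIDATE_DEGREES` that leave every
    leave-one-out fold determined (degree <= k - 2) compete on LOOCV RMSE
    under the one-standard-error rule: the lowest degree whose RMSE is
    within one standard error of the minimum wins. Candidates whose full
    fit swings far beyond the observed VA range inside the domain are
    excluded first — on a strongly uneven distance grid an overfitted
    high degree can oscillate by hundreds of letters between the sparse
    far nodes. Deterministic; ties break toward the lower degree.
    """
    k = len(points)
    if k < 3:
        raise InsufficientDataError(f"degree selection needs >= 3 points, got {k}")
    if k <= 5:
        return k - 1
    pts = sorted(points)
    x = np.asarray([p[0] for p in pts], float)
    y = np.asarray([p[1] for p in pts], float)
    a, b = float(x[0]), float(x[-1])
    cands = [d for d in CANDIDATE_DEGREES if d <= k - 2]
    plausible = [d for d in cands if _fit_in_range(x, y, d, a, b)]
    if not plausible:
        return cands[0]
    rmses = []
    ses = []
    for d in plausible:
        errs = _loocv_errors(x, y, d, a, b) ** 2
        mse = float(np.mean(errs))
        rmse = float(np.sqrt(mse))
        se_mse = float(np.std(errs, ddof=1) / np.sqrt(len(errs)))
        # delta method: se of sqrt(mse)
        ses.append(se_mse / (2.0 * rmse) if rmse > 0 else 0.0)
        rmses.append(rmse)
    i_best = int(np.argmin(rmses))
    threshold = rmses[i_best] + ses[i_best]
    for d, r in zip(plausible, rmses):
        if r <= threshold:
            return d
    return plausible[i_best]  # pragma: no cover


def _resolve_subset(subset: Union[str, DistanceSubset]) -> DistanceSubset:
    if isinstance(subset, str):
        try:
            return SUBSETS[subset]
        except KeyError:
            raise KeyError(f"unknown subset {subset!r}; known: {sorted(SUBSETS)}") from None
    return subset


def fit_vic(
    profile: VAProfile,
    subset: Union[str, DistanceSubset, None],
    x_axis: str = "cm",
    warn_range: bool = True,
) -> VisualCurve:
    """Fit the visual curve to a profile restricted to a distance subset.

    ``subset=None`` fits all points of the profile (used e.g. for custom
    measurement grids). The subset must not be the piecewise-linear
    comparator (``DCT``); use :func:`dct_aoc` for that. With
    ``x_axis='diopters'`` the independent variable is vergence x = 100/d
    (diopters) instead of distance in cm.
    """
    if subset is None:
        restricted = profile
        subset_id = f"ALL{len(profile.distances_cm)}"
    else:
        sub = _resolve_subset(subset)
        if sub.subset_id == "DCT":
            raise ValueError("DCT is the piecewise-linear comparator; use dct_aoc()")
        restricted = profile.restrict(sub.distances_cm)
        subset_id = sub.subset_id
    x, y = restricted.as_arrays()
    if x_axis == "diopters":
        order = np.argsort(100.0 / x)
        x, y = (100.0 / x)[order], y[order]
    elif x_axis != "cm":
        raise ValueError(f"x_axis must be 'cm' or 'diopters', got {x_axis!r}")

    degree = select_degree(list(zip(x, y)))
    a, b = float(x[0]), float(x[-1])
    V, pinv = _design(tuple(x), degree, a, b)
    coef_t = pinv @ y
    residuals = y - V @ coef_t
    cv = None
    if len(x) > 5:
        cv = _loocv_rmse(x, y, degree, a, b)
    raw = Polynomial(coef_t, domain=(a, b), window=(-1.0, 1.0)).convert().coef
    curve = VisualCurve(
        coefficients=tuple(float(c) for c in raw),
        domain=(a, b),
        degree=degree,
        subset_id=subset_id,
        residuals=tuple(float(r) for r in residuals),
        cv_rmse=cv,
        x_axis=x_axis,
    )
    if warn_range and curve.exits_va_range:
        warnings.warn(
            f"fitted curve for patient {profile.patient_id} (subset {sub.subset_id}) "
            "leaves the [0, 100] Letters range inside its domain",
            CurveRangeWarning,
            stacklevel=2,
        )
    return curve


def evaluate(curve: VisualCurve, x: float, allow_extrapolation: bool = False) -> float:
    """Polynomial value at ``x`` (same axis as the fit); raw, unclamped."""
    a, b = curve.domain
    tol = 1e-9 * (b - a)
    if not allow_extrapolation and not (a - tol <= x <= b + tol):
        raise DomainError(f"x = {x:g} outside the fitted domain [{a:g}, {b:g}]")
    return float(npoly.polyval(x, np.asarray(curve.coefficients)))


def aoc_indices(curve: VisualCurve, split_cm: float = NEAR_SPLIT_CM) -> AoCResult:
    """Analytic AoC of a fitted curve: total, near (<= split) and distance.

    Integration uses the closed-form antiderivative of the polynomial; no
    quadrature. The near/distance boundary is shared, so near + distance
    equals the total up to floating-point rounding.
    """
    a, b = curve.domain
    if curve.x_axis == "diopters":
        split = 100.0 / split_cm
    else:
        split = float(split_cm)
    if not (a < split < b):
        raise DomainError(
            f"split at {split:g} must lie strictly inside the domain [{a:g}, {b:g}]"
        )
    anti = npoly.polyint(np.asarray(curve.coefficients))
    F = lambda t: float(npoly.polyval(t, anti))  # noqa: E731
    total = F(b) - F(a)
    lower = F(split) - F(a)
    upper = F(b) - F(split)
    if curve.x_axis == "diopters":
        # large vergence = short distance: near vision is the upper part
        near, dist = upper, lower
    else:
        near, dist = lower, upper
    return AoCResult(total=total, near=near, distance=dist,
                     subset_id=curve.subset_id, method="polynomial")


def curve_area(curve: VisualCurve) -> float:
    """Analytic integral of the fitted polynomial over its whole domain."""
    a, b = curve.domain
    anti = npoly.polyint(np.asarray(curve.coefficients))
    return float(npoly.polyval(b, anti) - npoly.polyval(a, anti))


def dct_aoc(
    profile: VAProfile,
    split_cm: float = NEAR_SPLIT_CM,
    x_axis: str = "cm",
) -> AoCResult:
    """AoC of the conventional defocus-curve comparator.

    Straight lines connect every measured point; areas are exact trapezoid
    sums. If the split is not a measurement node the piecewise-linear
    interpolant is evaluated there and the containing trapezoid divided, so
    near + distance = total exactly.
    """
    x, y = profile.as_arrays()
    if x_axis == "diopters":
        order = np.argsort(100.0 / x)
        x, y = (100.0 / x)[order], y[order]
        split = 100.0 / split_cm
    elif x_axis == "cm":
        split = float(split_cm)
    else:
        raise ValueError(f"x_axis must be 'cm' or 'diopters', got {x_axis!r}")
    if not (x[0] < split < x[-1]):
        raise DomainError(
            f"split at {split:g} must lie strictly inside [{x[0]:g}, {x[-1]:g}]"
        )
    if split not in x:
        ys = float(np.interp(split, x, y))
        i = int(np.searchsorted(x, split))
        x = np.insert(x, i, split)
        y = np.insert(y, i, ys)
    i = int(np.where(x == split)[0][0])
    lower = float(np.trapezoid(y[: i + 1], x[: i + 1]))
    upper = float(np.trapezoid(y[i:], x[i:]))
    if x_axis == "diopters":
        near, dist = upper, lower
    else:
        near, dist = lower, upper
    return AoCResult(total=near + dist, near=near, distance=dist,
                     subset_id="DCT", method="piecewise_linear")


# --------------------------------------------------------------------------
# cohort-level table

def aoc_table(
    profiles: Iterable[VAProfile],
    subsets: Sequence[str] = ALL_SUBSETS,
    split_cm: float = NEAR_SPLIT_CM,
    x_axis: str = "cm",
    warn_range: bool = False,
) -> pd.DataFrame:
    """Tidy per-patient AoC index table.

    One row per patient and subset with columns ``patient_id, subset,
    method, aoc_total, aoc_near, aoc_distance``. With the default five
    subsets this is 15 index values per patient. Any per-patient fit error
    aborts the whole table (complete-case analysis) with the patient id
    attached.
    """
    rows = []
    for profile in profiles:
        try:
            for sid in subsets:
                if sid == "DCT":
                    res = dct_aoc(profile, split_cm=split_cm, x_axis=x_axis)
                else:
                    curve = fit_vic(profile, sid, x_axis=x_axis, warn_range=warn_range)
                    res = aoc_indices(curve, split_cm=split_cm)
                rows.append(
                    (profile.patient_id, res.subset_id, res.method,
                     res.total, res.near, res.distance)
                )
        except Exception as exc:  # complete-case: one bad fit fails the table
            raise PipelineError("aoc_table", f"patient {profile.patient_id}: {exc}") from exc
    return pd.DataFrame(
        rows,
        columns=["patient_id", "subset", "method",
                 "aoc_total", "aoc_near", "aoc_distance"],
    )


def aoc_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy AoC table to one row per patient.

    Columns are named ``total_S9``, ``near_DCT``, ... (15 columns for the
    full subset battery), matching the index names used by the statistics
    module.
    """
    long = table.melt(
        id_vars=["patient_id", "subset"],
        value_vars=["aoc_total", "aoc_near", "aoc_distance"],
        var_name="which", value_name="value",
    )
    long["index_name"] = long["which"].str.replace("aoc_", "", regex=False) + "_" + long["subset"]
    wide = long.pivot(index="patient_id", columns="index_name", values="value")
    wide.columns.name = None
    return wide
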