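"""Stand-structure metrics: DBH classes, age grades, density, canopy cover
and DBH-class population-structure fits.

DBH (cm) is binned into 21 contiguous 4-cm classes — class k covers
(4(k-1), 4k] and the open-ended class 21 collects everything above 80 cm —
and, as an age proxy, into four grades: young (1, 15], near-mature (15, 30],
mature (30, 50] and old (50, inf) cm.  All intervals are closed on the right.

The class histogram of a stand is summarised by two candidate nonlinear
least-squares fits: a decreasing logistic a / (1 + b e^{c k}) (the reversed-J
shape of a regenerating population) and a Gaussian bell a e^{-(k-mu)^2 /
(2 sigma^2)} (a stand dominated by intermediate size classes).  The model
with the higher R^2, together with the age-grade percentages, yields a
population trend label: growing, stable or temporarily stable.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .stand_model import TreeRecord, Window

__all__ = [
    "GRADES",
    "N_DBH_CLASSES",
    "FitError",
    "PopulationFit",
    "StandSummary",
    "assign_dbh_class",
    "assign_age_grade",
    "stand_density_index",
    "crown_projection_area",
    "dbh_class_histogram",
    "fit_population_model",
    "classify_population_trend",
    "stand_summary",
]

GRADES = ("young", "near_mature", "mature", "old")
#: Right-closed grade boundaries in cm: (1,15], (15,30], (30,50], (50,inf).
GRADE_BOUNDS = (1.0, 15.0, 30.0, 50.0, math.inf)

N_DBH_CLASSES = 21
_CLASS_WIDTH = 4.0
_OPEN_CLASS_FLOOR = 80.0  # DBH above this pools into class 21


class FitError(Exception):
    """Raised when a population-structure curve fit is not possible."""


def assign_dbh_class(dbh: float) -> int:
    """4-cm DBH class index in 1..21; class k covers (4(k-1), 4k] cm.

    Class 21 is open-ended and collects all stems above 80 cm.
    """
    if dbh <= 0:
        raise ValueError(f"dbh must be > 0, got {dbh}")
    if dbh > _OPEN_CLASS_FLOOR:
        return N_DBH_CLASSES
    # right-closed bins: 4.0 -> class 1, 4.0 + eps -> class 2
    return max(1, int(math.ceil(dbh / _CLASS_WIDTH - 1e-12)))


def assign_age_grade(dbh: float) -> str:
    """Age grade from DBH: young (1,15], near_mature (15,30], mature (30,50], old (50,inf)."""
    if dbh <= GRADE_BOUNDS[0]:
        raise ValueError(f"dbh must be > {GRADE_BOUNDS[0]} cm, got {dbh}")
    for grade, hi in zip(GRADES, GRADE_BOUNDS[1:]):
        if dbh <= hi:
            return grade
    raise AssertionError("unreachable")


def stand_density_index(n_trees: int, area_ha: float) -> float:
    """Stand density index: trees per hectare (unrounded).

    Reported values in output tables are rounded to the nearest integer.
    """
    if area_ha <= 0:
        raise ValueError(f"area must be > 0 ha, got {area_ha}")
    if n_trees < 0:
        raise ValueError(f"n_trees must be >= 0, got {n_trees}")
    return n_trees / area_ha


def crown_projection_area(
    trees: Sequence[TreeRecord], window: Window, cell: float = 0.1
) -> float:
    """Percent of the plot covered by the union of crown projections.

    Crowns are discs centred on the stem with diameter CD, clipped at the
    window boundary.  The union area is evaluated on a raster of ``cell``-m
    square cells with a cell-centre inclusion test, so overlapping crowns are
    never double counted.
    """
    if cell <= 0:
        raise ValueError(f"cell must be > 0, got {cell}")
    if cell > min(window.width, window.height):
        raise ValueError(
            f"cell {cell} m exceeds the smaller window side "
            f"{min(window.width, window.height)} m"
        )
    if not trees:
        return 0.0
    nx = int(round(window.width / cell))
    ny = int(round(window.height / cell))
    xs = window.x_min + (np.arange(nx) + 0.5) * cell
    ys = window.y_min + (np.arange(ny) + 0.5) * cell
    covered = np.zeros((ny, nx), dtype=bool)
    for t in trees:
        r = t.cd / 2.0
        if r <= 0:
            continue
        ix0 = np.searchsorted(xs, t.x - r)
        ix1 = np.searchsorted(xs, t.x + r, side="right")
        iy0 = np.searchsorted(ys, t.y - r)
        iy1 = np.searchsorted(ys, t.y + r, side="right")
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        dx = xs[ix0:ix1] - t.x
        dy = ys[iy0:iy1] - t.y
        inside = dx[None, :] ** 2 + dy[:, None] ** 2 <= r * r
        covered[iy0:iy1, ix0:ix1] |= inside
    return 100.0 * covered.mean()


def dbh_class_histogram(
    trees: Iterable[TreeRecord] | Iterable[float],
) -> tuple[np.ndarray, dict[str, int]]:
    """Counts per 4-cm DBH class (length 21) and per age grade.

    Accepts TreeRecords or raw DBH values (cm).  Grade counts are derived
    from the same stems, so both tally to the total tree count.
    """
    counts = np.zeros(N_DBH_CLASSES, dtype=int)
    grades = {g: 0 for g in GRADES}
    for t in trees:
        dbh = t.dbh if isinstance(t, TreeRecord) else float(t)
        counts[assign_dbh_class(dbh) - 1] += 1
        grades[assign_age_grade(dbh)] += 1
    return counts, grades


# ---------------------------------------------------------------------------
# Population-structure fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationFit:
    """Best-fitting DBH-class curve and its goodness of fit.

    ``candidates`` records (parameters, R^2) for both model forms so the
    runner-up fit remains inspectable.
    """

    model: str  # "logistic_decreasing" | "gaussian"
    parameters: tuple[float, ...]
    r_squared: float
    candidates: Mapping[str, tuple[tuple[float, ...], float]]


def _logistic_decreasing(k, a, b, c):
    return a / (1.0 + b * np.exp(c * k))


def _gaussian(k, a, mu, sigma):
    return a * np.exp(-((k - mu) ** 2) / (2.0 * sigma**2))


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _fit_multistart(f, k, y, starts, bounds):
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    f, k, y, p0=p0, bounds=bounds, maxfev=500, xtol=1e-8, ftol=1e-8
                )
        except (RuntimeError, ValueError):
            continue
        r2 = _r_squared(y, f(k, *popt))
        if best is None or r2 > best[1]:
            best = (tuple(float(v) for v in popt), r2)
    return best


def fit_population_model(counts: Sequence[int] | np.ndarray) -> PopulationFit:
    """Fit both candidate curves to the DBH-class histogram, keep the better.

    ``counts`` is the per-class histogram over classes 1..21 (trailing zero
    classes may be omitted).  Requires at least 4 non-empty classes.  Ties in
    R^2 go to the Gaussian.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or np.any(y < 0):
        raise ValueError("counts must be a 1-D non-negative histogram")
    if np.count_nonzero(y) < 4:
        raise FitError(
            f"need >= 4 non-empty DBH classes, got {np.count_nonzero(y)}"
        )
    k = np.arange(1, len(y) + 1, dtype=float)
    a0 = float(y.max())

    # five fixed multistarts for the decreasing logistic: midpoint k0 and rate c
    log_starts = [
        (a0, math.exp(c * k0), c)
        for k0, c in ((4.0, 0.3), (6.0, 0.5), (8.0, 0.5), (8.0, 1.0), (12.0, 0.3))
    ]
    log_best = _fit_multistart(
        _logistic_decreasing, k, y, log_starts,
        bounds=([1e-9, 1e-12, 1e-6], [np.inf, np.inf, 10.0]),
    )

    mu0 = float(k[int(np.argmax(y))])
    gauss_starts = [(a0, mu0, 2.0), (a0, mu0, 4.0), (a0, float(np.sum(k * y) / y.sum()), 3.0)]
    gauss_best = _fit_multistart(
        _gaussian, k, y, gauss_starts,
        bounds=([1e-9, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
    )

    if log_best is None and gauss_best is None:
        raise FitError("neither candidate model converged on this histogram")
    candidates = {}
    if log_best is not None:
        candidates["logistic_decreasing"] = log_best
    if gauss_best is not None:
        candidates["gaussian"] = gauss_best
    # ties go to the Gaussian
    if gauss_best is not None and (log_best is None or gauss_best[1] >= log_best[1]):
        model = "gaussian"
    else:
        model = "logistic_decreasing"
    params, r2 = candidates[model]
    return PopulationFit(model=model, parameters=params, r_squared=r2, candidates=candidates)


def classify_population_trend(
    grade_percentages: Mapping[str, float],
    best_model: str | None,
    young_stable_threshold: float = 15.0,
) -> str:
    """Trend label from the grade mix and the best-fitting curve form.

    growing
        reversed-J class structure (decreasing logistic) with more young
        than old trees;
    stable
        otherwise, provided young trees still hold at least
        ``young_stable_threshold`` percent;
    temporarily_stable
        otherwise (regeneration too scarce to sustain the stand).
    """
    young = float(grade_percentages.get("young", 0.0))
    old = float(grade_percentages.get("old", 0.0))
    if best_model == "logistic_decreasing" and young > old:
        return "growing"
    if young >= young_stable_threshold:
        return "stable"
    return "temporarily_stable"


# ---------------------------------------------------------------------------
# Per-stand summary (one output-table row)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandSummary:
    """Descriptive stand attributes for one plot or one pooled transect."""

    n_trees: int
    grade_percentages: dict[str, float]  # sums to 100 up to rounding
    sdi: float  # trees per hectare, unrounded
    mean_th: float
    sd_th: float
    mean_dbh: float
    sd_dbh: float
    mean_cd: float
    sd_cd: float
    cpa: float  # percent canopy cover


def stand_summary(
    trees: Sequence[TreeRecord], window: Window, area_ha: float | None = None,
    cpa_cell: float = 0.1,
) -> StandSummary:
    """Summarise a stand: density, grade mix, biometric means +- sd, CPA.

    ``area_ha`` defaults to the window area; pass the pooled area when
    summarising several plots together.  Standard deviations use the
    population denominator n.
    """
    area_ha = window.area_ha if area_ha is None else area_ha
    n = len(trees)
    _, grades = dbh_class_histogram(trees)
    pct = {g: (100.0 * grades[g] / n if n else 0.0) for g in GRADES}
    if n:
        th = np.array([t.th for t in trees])
        dbh = np.array([t.dbh for t in trees])
        cd = np.array([t.cd for t in trees])
        stats = (
            float(th.mean()), float(th.std()),
            float(dbh.mean()), float(dbh.std()),
            float(cd.mean()), float(cd.std()),
        )
    else:
        stats = (0.0,) * 6
    return StandSummary(
        n_trees=n,
        grade_percentages=pct,
        sdi=stand_density_index(n, area_ha),
        mean_th=stats[0], sd_th=stats[1],
        mean_dbh=stats[2], sd_dbh=stats[3],
        mean_cd=stats[4], sd_cd=stats[5],
        cpa=crown_projection_area(trees, window, cell=cpa_cell),
    )
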