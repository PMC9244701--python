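"""Scalar aggregation indices: average nearest neighbour (Clark-Evans),
Hopkins-Skellam, David-Moore (index of clumping) and Morisita's I_delta.

Direction conventions
---------------------
ANN < 1 signals aggregation and ANN > 1 regularity; the other three indices
run the opposite way (> 1 aggregated, < 1 regular).  Each index comes with a
standardised score and a significance flag: ANN uses the analytic
Clark-Evans normal test, the others a seeded Monte-Carlo CSR null
(standardised score = (value - null mean) / null sd, two-sided rank p).
A non-significant index is labelled random regardless of direction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .stand_model import Window

__all__ = [
    "IndexResult",
    "QuadratCounts",
    "ann_index",
    "hopkins_skellam",
    "quadrat_counts",
    "david_moore",
    "morisita",
    "nearest_neighbor_distances",
]

_DEFAULT_ALPHA = 0.05
_Z_CRIT = 1.959963984540054  # two-sided 5% normal quantile


@dataclass(frozen=True)
class IndexResult:
    """A scalar aggregation index with its test statistic and label."""

    index_name: str  # ANN | HSI | DMI | Morisita
    value: float
    score: float  # z for ANN; Monte-Carlo standardised score otherwise
    p_value: float
    significant: bool
    label: str  # aggregated | random | regular


@dataclass(frozen=True)
class QuadratCounts:
    """Tree counts over a square-quadrat grid exactly tiling the window."""

    counts: np.ndarray  # flat, length q
    quadrat_side: float
    shape: tuple[int, int]  # (rows, cols)

    @property
    def q(self) -> int:
        return int(self.counts.size)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be an (n, 2) array, got shape {pts.shape}")
    return pts


def nearest_neighbor_distances(points) -> np.ndarray:
    """Distance from each point to its nearest other point."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def _direction_label(value: float, significant: bool, greater_is_aggregated: bool) -> str:
    if not significant:
        return "random"
    if (value > 1.0) == greater_is_aggregated:
        return "aggregated"
    return "regular"


def ann_index(points, window: Window, correction: str = "none") -> IndexResult:
    """Average nearest neighbour ratio (Clark-Evans index) with z test.

    ANN = mean NN distance / (0.5 sqrt(A/n)); its standard error under CSR
    is 0.26136 / sqrt(n^2 / A).  ``correction="donnelly"`` adds the Donnelly
    perimeter adjustment to the CSR expectation; the default applies none.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    a = window.area
    d_obs = float(nearest_neighbor_distances(pts).mean())
    d_exp = 0.5 * math.sqrt(a / n)
    if correction == "donnelly":
        perim = 2.0 * (window.width + window.height)
        d_exp += (0.0514 + 0.041 / math.sqrt(n)) * perim / n
    elif correction != "none":
        raise ValueError(f"unknown ANN correction {correction!r}")
    se = 0.26136 / math.sqrt(n * n / a)
    z = (d_obs - d_exp) / se
    from scipy.stats import norm

    p = 2.0 * float(norm.sf(abs(z)))
    significant = abs(z) > _Z_CRIT
    value = d_obs / d_exp
    return IndexResult(
        index_name="ANN",
        value=value,
        score=z,
        p_value=p,
        significant=significant,
        label=_direction_label(value, significant, greater_is_aggregated=False),
    )


def _mc_standardize(value: float, null_values: np.ndarray) -> tuple[float, float, bool]:
    sd = float(null_values.std())
    mean = float(null_values.mean())
    score = (value - mean) / sd if sd > 0 else math.inf * np.sign(value - mean)
    m = len(null_values)
    n_ge = int(np.sum(null_values >= value)) + 1
    n_le = int(np.sum(null_values <= value)) + 1
    p = min(1.0, 2.0 * min(n_ge, n_le) / (m + 1))
    return score, p, p < _DEFAULT_ALPHA


def hopkins_skellam(
    points,
    window: Window,
    n_sample: int | None = None,
    seed: int | None = None,
    n_sim: int = 199,
) -> IndexResult:
    """Hopkins-Skellam coefficient of aggregation.

    HSI = sum P_i^2 / sum I_i^2, with P_i the distance from each of
    ``n_sample`` uniform random locations to the nearest tree and I_i the
    distance from each of ``n_sample`` randomly chosen trees to their
    nearest other tree.  n_sample defaults to min(n, 100); values above n
    are clamped with a warning.  Significance by a seeded Monte-Carlo CSR
    null with the same n and sampling rule.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    if n_sample is None:
        n_sample = min(n, 100)
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    if n_sample > n:
        warnings.warn(
            f"n_sample {n_sample} exceeds n={n}; clamped to n", stacklevel=2
        )
        n_sample = n

    rng = np.random.default_rng(seed)

    def _hsi(p: np.ndarray, sub: np.random.Generator) -> float:
        tree = cKDTree(p)
        random_pts = np.column_stack(
            (
                sub.uniform(window.x_min, window.x_max, n_sample),
                sub.uniform(window.y_min, window.y_max, n_sample),
            )
        )
        p_dist, _ = tree.query(random_pts, k=1)
        chosen = sub.choice(len(p), size=n_sample, replace=False)
        i_dist, _ = tree.query(p[chosen], k=2)
        i_dist = i_dist[:, 1]
        return float(np.sum(p_dist**2) / np.sum(i_dist**2))

    value = _hsi(pts, rng)
    null = np.empty(n_sim)
    for s in range(n_sim):
        sim = np.column_stack(
            (
                rng.uniform(window.x_min, window.x_max, n),
                rng.uniform(window.y_min, window.y_max, n),
            )
        )
        null[s] = _hsi(sim, rng)
    score, p, significant = _mc_standardize(value, null)
    return IndexResult(
        index_name="HSI",
        value=value,
        score=score,
        p_value=p,
        significant=significant,
        label=_direction_label(value, significant, greater_is_aggregated=True),
    )


def quadrat_counts(points, window: Window, quadrat_side: float = 10.0) -> QuadratCounts:
    """Counts over a grid of square quadrats exactly tiling the window.

    ``quadrat_side`` must divide both window sides; otherwise an error lists
    the valid sides.
    """
    pts = _as_points(points)
    nx = window.width / quadrat_side
    ny = window.height / quadrat_side
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        valid = [
            window.width / k
            for k in range(1, int(window.width) + 1)
            if (window.width / k) % 1 == 0 and (window.height / (window.width / k)) % 1 == 0
        ]
        raise ValueError(
            f"quadrat side {quadrat_side} does not tile the "
            f"{window.width} x {window.height} window; valid sides include {valid}"
        )
    nx, ny = int(round(nx)), int(round(ny))
    ix = np.clip(((pts[:, 0] - window.x_min) / quadrat_side).astype(int), 0, nx - 1)
    iy = np.clip(((pts[:, 1] - window.y_min) / quadrat_side).astype(int), 0, ny - 1)
    flat = np.bincount(iy * nx + ix, minlength=nx * ny)
    return QuadratCounts(counts=flat, quadrat_side=quadrat_side, shape=(ny, nx))


def _multinomial_null(n: int, q: int, n_sim: int, rng: np.random.Generator, stat) -> np.ndarray:
    # CSR conditioned on n over q equal quadrats is uniform multinomial
    draws = rng.multinomial(n, np.full(q, 1.0 / q), size=n_sim)
    return np.array([stat(x) for x in draws], dtype=float)


def _dmi_value(x: np.ndarray) -> float:
    q = len(x)
    xbar = x.mean()
    return float(np.sum((x - xbar) ** 2) / (xbar * (q - 1)))


def _morisita_value(x: np.ndarray) -> float:
    n_total = int(x.sum())
    return float(len(x) * np.sum(x * (x - 1.0)) / (n_total * (n_total - 1.0)))


def david_moore(
    counts: QuadratCounts, n_sim: int = 199, seed: int | None = 0
) -> IndexResult:
    """David-Moore index of clumping: the quadrat variance-to-mean ratio.

    DMI = sum (x_i - xbar)^2 / (xbar (q - 1)); 1 under Poisson counts,
    > 1 clumped, < 1 regular.  Significance by a seeded multinomial
    Monte-Carlo CSR null.
    """
    x = np.asarray(counts.counts, dtype=float)
    if counts.q < 2:
        raise ValueError("need at least 2 quadrats")
    if x.mean() == 0:
        raise ValueError("mean quadrat count is zero; DMI undefined")
    value = _dmi_value(x)
    rng = np.random.default_rng(seed)
    null = _multinomial_null(counts.n, counts.q, n_sim, rng, _dmi_value)
    score, p, significant = _mc_standardize(value, null)
    return IndexResult(
        index_name="DMI",
        value=value,
        score=score,
        p_value=p,
        significant=significant,
        label=_direction_label(value, significant, greater_is_aggregated=True),
    )


def morisita(
    counts: QuadratCounts, n_sim: int = 199, seed: int | None = 0
) -> IndexResult:
    """Morisita's index I_delta = q sum x_i (x_i - 1) / (N (N - 1)).

    1 under random mixing; maximal (= q) when all N trees share one quadrat.
    Significance by a seeded multinomial Monte-Carlo CSR null.
    """
    x = np.asarray(counts.counts, dtype=float)
    if counts.n < 2:
        raise ValueError(f"need at least 2 trees, got {counts.n}")
    value = _morisita_value(x)
    rng = np.random.default_rng(seed)
    null = _multinomial_null(counts.n, counts.q, n_sim, rng, _morisita_value)
    score, p, significant = _mc_standardize(value, null)
    return IndexResult(
        index_name="Morisita",
        value=value,
        score=score,
        p_value=p,
        significant=significant,
        label=_direction_label(value, significant, greater_is_aggregated=True),
    )
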