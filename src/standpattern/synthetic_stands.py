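"""Seeded generators for synthetic riparian-stand studies.

The generators emulate an 18-plot design: three river transects (upper,
middle, lower), each with six 50 m x 50 m plots at 20, 200, 400, 600, 800
and 1000 m from the river channel.  Stem positions come from one of three
point processes —

* CSR (binomial: a fixed number of uniform points),
* a Thomas cluster process (Poisson parents with Poisson numbers of
  Gaussian-dispersed offspring; the canonical aggregated pattern with a
  closed-form pair correlation), and
* simple sequential inhibition (a hardcore minimum spacing; the canonical
  regular pattern) —

with densities and aggregation increasing downstream: upper plots are
essentially random and densest (~113 trees/plot), middle plots mix random
near the river with clustered beyond 200 m (~95 trees/plot), and lower
plots are clustered and sparsest (~66 trees/plot).  The sixth upper plot
(1000 m from the river) is mildly clustered.

Biometric marks are drawn from per-transect age-grade mixes.  Grades are
assigned by largest-remainder quota so each plot reproduces its transect's
grade percentages up to integer rounding (the grade shares are study
conditions, not sampling noise).  DBH within a grade follows a linear
("tilted") density on the grade interval — uniform by default, decreasing
in the upper transect so the pooled class histogram takes the reversed-J
shape of a regenerating stand — with old trees capped at 100 cm.  Heights
and crowns follow power-law allometries TH = alpha DBH^beta and
CD = alpha' DBH^beta' with multiplicative lognormal noise.  Abiotic covariates follow downstream and
distance-from-river gradients — groundwater depth and soil moisture
decrease downstream and away from the river, conductance increases — with
Gaussian noise at 10% of each gradient's range.

All randomness flows from one master seed; each plot uses a substream
derived from (seed, plot index), so any plot regenerates independently and
the same seed reproduces the study bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .stand_model import PlotData, TreeRecord, Window, DEFAULT_WINDOW
from .structure_metrics import GRADES

__all__ = [
    "AllometryConfig",
    "TransectSettings",
    "SyntheticStudyConfig",
    "thomas_pair_correlation",
    "simulate_csr",
    "simulate_thomas",
    "simulate_thomas_conditional",
    "simulate_inhibition",
    "attach_marks",
    "generate_study",
]

#: Right-closed DBH intervals (cm) per age grade used when drawing marks;
#: the open-ended old grade is capped at 100 cm.
GRADE_DBH_INTERVALS = {
    "young": (1.0, 15.0),
    "near_mature": (15.0, 30.0),
    "mature": (30.0, 50.0),
    "old": (50.0, 100.0),
}


@dataclass(frozen=True)
class AllometryConfig:
    """Power-law height and crown allometries with lognormal noise.

    Defaults give TH ~ 10 m and CD ~ 4.5 m at DBH 25 cm, matching a mature
    desert-poplar stand.
    """

    th_coef: float = 1.49
    th_exp: float = 0.6
    th_sd: float = 0.15  # sd of log-scale multiplicative noise
    cd_coef: float = 0.9
    cd_exp: float = 0.5
    cd_sd: float = 0.15


@dataclass(frozen=True)
class TransectSettings:
    """Per-transect generator settings.

    ``dbh_tilts`` sets the linear within-grade DBH density per grade:
    0 is uniform, +1 a triangular density decreasing to zero at the grade's
    upper bound (front-loaded, small stems dominate), -1 the mirror image.
    """

    mean_trees: int  # target trees per plot
    grade_mix: tuple[float, float, float, float]  # young/near/mature/old
    #: distances (m) at which plots are clustered rather than CSR
    clustered_beyond: float  # plots with DR > this use the Thomas process
    thomas_sigma: float = 2.0
    thomas_mu: float = 25.0
    dbh_tilts: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


def _default_transects() -> dict[str, TransectSettings]:
    return {
        # grade mixes follow the per-transect age-structure percentages;
        # the upper transect's decreasing tilts produce the reversed-J
        # class histogram of a regenerating stand
        "upper": TransectSettings(
            mean_trees=113,
            grade_mix=(0.29, 0.43, 0.23, 0.05),
            clustered_beyond=800.0,  # only the 1000-m plot is (mildly) clustered
            thomas_sigma=4.0,
            thomas_mu=10.0,
            dbh_tilts=(1.0, 0.5, 1.0, 1.0),
        ),
        "middle": TransectSettings(
            mean_trees=95,
            grade_mix=(0.18, 0.45, 0.26, 0.11),
            clustered_beyond=200.0,
        ),
        "lower": TransectSettings(
            mean_trees=66,
            grade_mix=(0.14, 0.48, 0.29, 0.09),
            clustered_beyond=0.0,  # all lower plots clustered
        ),
    }


@dataclass(frozen=True)
class AbioticGradients:
    """Linear downstream/distance gradients for the abiotic covariates.

    Each covariate is transect offset + slope x distance-from-river plus
    Gaussian noise with sd = ``noise_fraction`` of the covariate's range
    across the study.  Groundwater depth (gd, m) and soil moisture (sm,
    vol-%) decrease downstream and with distance; conductance (sc, mS/cm)
    increases; pH is flat apart from noise.
    """

    gd_offsets: tuple[float, float, float] = (8.0, 6.0, 4.0)  # upper/middle/lower
    gd_slope: float = -0.002
    sm_offsets: tuple[float, float, float] = (22.0, 16.0, 10.0)
    sm_slope: float = -0.005
    sc_offsets: tuple[float, float, float] = (0.8, 1.6, 2.4)
    sc_slope: float = 0.0008
    ph_offset: float = 8.1
    noise_fraction: float = 0.1


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Full configuration of the 18-plot synthetic study."""

    window: Window = DEFAULT_WINDOW
    distances: tuple[float, ...] = (20.0, 200.0, 400.0, 600.0, 800.0, 1000.0)
    transects: dict[str, TransectSettings] = field(default_factory=_default_transects)
    allometry: AllometryConfig = AllometryConfig()
    abiotic: AbioticGradients = AbioticGradients()
    seed: int = 0

    def with_seed(self, seed: int) -> "SyntheticStudyConfig":
        return replace(self, seed=seed)


def thomas_pair_correlation(r, kappa: float, sigma: float) -> np.ndarray:
    """Closed-form pair correlation of the (modified) Thomas process:

    g(r) = 1 + exp(-r^2 / (4 sigma^2)) / (4 pi sigma^2 kappa).
    """
    r = np.asarray(r, dtype=float)
    return 1.0 + np.exp(-(r**2) / (4.0 * sigma**2)) / (4.0 * np.pi * sigma**2 * kappa)


def simulate_csr(n: int, window: Window, seed=None) -> np.ndarray:
    """n i.i.d. uniform points in the window (binomial process)."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    return np.column_stack(
        (
            rng.uniform(window.x_min, window.x_max, n),
            rng.uniform(window.y_min, window.y_max, n),
        )
    )


def simulate_thomas(
    kappa: float, sigma: float, mu: float, window: Window, seed=None
) -> np.ndarray:
    """Thomas cluster process clipped to the window.

    Parents are Poisson(kappa) per m^2 on the window extended by 4 sigma on
    every side (so edge clusters contribute); each parent gets Poisson(mu)
    offspring with isotropic Gaussian(sigma) offsets.  Expected count inside
    the window is kappa * area * mu.
    """
    if kappa <= 0 or sigma <= 0 or mu <= 0:
        raise ValueError("kappa, sigma and mu must all be > 0")
    rng = np.random.default_rng(seed)
    pad = 4.0 * sigma
    ext_w = window.width + 2 * pad
    ext_h = window.height + 2 * pad
    n_parents = rng.poisson(kappa * ext_w * ext_h)
    px = rng.uniform(window.x_min - pad, window.x_max + pad, n_parents)
    py = rng.uniform(window.y_min - pad, window.y_max + pad, n_parents)
    n_off = rng.poisson(mu, n_parents)
    cx = np.repeat(px, n_off) + rng.normal(0.0, sigma, int(n_off.sum()))
    cy = np.repeat(py, n_off) + rng.normal(0.0, sigma, int(n_off.sum()))
    keep = (
        (cx >= window.x_min) & (cx <= window.x_max)
        & (cy >= window.y_min) & (cy <= window.y_max)
    )
    return np.column_stack((cx[keep], cy[keep]))


def simulate_thomas_conditional(
    n: int, kappa: float, sigma: float, window: Window, seed=None
) -> np.ndarray:
    """Thomas-type cluster pattern conditioned on exactly n points in window.

    Parents are Poisson(kappa) per m^2 on the window extended by 4 sigma (at
    least one parent); each of the n points picks a parent uniformly and
    takes a Gaussian(sigma) offset, redrawing the offset until it lands
    inside the window.  Used by the study generator so plot densities are
    design conditions rather than Poisson noise; for the unconditional
    process with its closed-form pair correlation use :func:`simulate_thomas`.
    """
    if n < 0 or kappa <= 0 or sigma <= 0:
        raise ValueError("need n >= 0 and kappa, sigma > 0")
    rng = np.random.default_rng(seed)
    pad = 4.0 * sigma
    n_parents = max(1, rng.poisson(kappa * (window.width + 2 * pad) * (window.height + 2 * pad)))
    px = rng.uniform(window.x_min - pad, window.x_max + pad, n_parents)
    py = rng.uniform(window.y_min - pad, window.y_max + pad, n_parents)
    out = np.empty((n, 2))
    placed = 0
    while placed < n:
        m = n - placed
        parent = rng.integers(0, n_parents, m)
        x = px[parent] + rng.normal(0.0, sigma, m)
        y = py[parent] + rng.normal(0.0, sigma, m)
        ok = (
            (x >= window.x_min) & (x <= window.x_max)
            & (y >= window.y_min) & (y <= window.y_max)
        )
        k = int(ok.sum())
        out[placed : placed + k, 0] = x[ok]
        out[placed : placed + k, 1] = y[ok]
        placed += k
    return out


def simulate_inhibition(
    n: int, r_min: float, window: Window, seed=None, max_attempts: int = 200_000
) -> np.ndarray:
    """Simple sequential inhibition: n points, all pairwise distances >= r_min.

    Uniform proposals are accepted unless they fall within r_min of an
    accepted point.  Raises a RuntimeError reporting the number of points
    achieved if ``max_attempts`` proposals are exhausted first.
    """
    if n < 0 or r_min <= 0:
        raise ValueError("need n >= 0 and r_min > 0")
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, 2))
    k = 0
    attempts = 0
    batch = max(64, n)
    while k < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"inhibition sampler placed only {k} of {n} points at "
                f"r_min={r_min} after {max_attempts} proposals"
            )
        m = min(batch, max_attempts - attempts)
        props = np.column_stack(
            (
                rng.uniform(window.x_min, window.x_max, m),
                rng.uniform(window.y_min, window.y_max, m),
            )
        )
        attempts += m
        for p in props:
            if k and np.min(np.sum((accepted[:k] - p) ** 2, axis=1)) < r_min**2:
                continue
            accepted[k] = p
            k += 1
            if k == n:
                break
    return accepted.copy()


def _tilted_uniform(n: int, tilt: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n values in [0, 1] with linear density 1 + tilt (1 - 2u).

    tilt = 0 is uniform; tilt = +1 a triangular density decreasing to zero
    at 1; tilt = -1 its mirror image.  Sampled by CDF inversion.
    """
    if not -1.0 <= tilt <= 1.0:
        raise ValueError(f"tilt must lie in [-1, 1], got {tilt}")
    u = rng.uniform(0.0, 1.0, n)
    if tilt == 0.0:
        return u
    # invert F(v) = (1 + tilt) v - tilt v^2
    return ((1.0 + tilt) - np.sqrt((1.0 + tilt) ** 2 - 4.0 * tilt * u)) / (2.0 * tilt)


def _quota_counts(n: int, mix: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n trees to the four grades."""
    exact = mix * n
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    for gi in np.argsort(-rem)[: n - counts.sum()]:
        counts[gi] += 1
    return counts


def attach_marks(
    positions: np.ndarray,
    grade_mix: Sequence[float],
    allometry: AllometryConfig = AllometryConfig(),
    seed=None,
    id_prefix: str = "t",
    dbh_tilts: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
) -> list[TreeRecord]:
    """Assign biometric marks to stem positions.

    Age grades (young, near-mature, mature, old) are apportioned by
    largest-remainder quota from ``grade_mix`` and shuffled over positions,
    so every stand reproduces the mix up to integer rounding.  DBH is drawn
    within the grade's interval with the grade's linear tilt (0 = uniform);
    TH and CD follow the power-law allometries with seeded multiplicative
    lognormal noise.
    """
    mix = np.asarray(grade_mix, dtype=float)
    if mix.ndim != 1 or len(mix) != 4 or np.any(mix < 0) or mix.sum() <= 0:
        raise ValueError("grade_mix must be 4 non-negative proportions")
    mix = mix / mix.sum()
    rng = np.random.default_rng(seed)
    n = len(positions)
    counts = _quota_counts(n, mix)
    grades = rng.permutation(np.repeat(np.arange(4), counts))
    dbh_all = np.empty(n)
    for gi in range(4):
        sel = grades == gi
        lo, hi = GRADE_DBH_INTERVALS[GRADES[gi]]
        dbh_all[sel] = lo + (hi - lo) * _tilted_uniform(
            int(sel.sum()), float(dbh_tilts[gi]), rng
        )
    trees = []
    for i, ((x, y), dbh) in enumerate(zip(positions, dbh_all)):
        th = allometry.th_coef * dbh**allometry.th_exp * rng.lognormal(0.0, allometry.th_sd)
        cd = allometry.cd_coef * dbh**allometry.cd_exp * rng.lognormal(0.0, allometry.cd_sd)
        trees.append(
            TreeRecord(tree_id=f"{id_prefix}{i + 1:04d}", x=float(x), y=float(y),
                       th=float(th), dbh=float(dbh), cd=float(cd))
        )
    return trees


def _plot_positions(
    transect: str, settings: TransectSettings, distance: float,
    window: Window, seed_seq,
) -> np.ndarray:
    if distance > settings.clustered_beyond:
        kappa = settings.mean_trees / (window.area * settings.thomas_mu)
        return simulate_thomas_conditional(
            settings.mean_trees, kappa, settings.thomas_sigma, window, seed_seq
        )
    return simulate_csr(settings.mean_trees, window, seed_seq)


def generate_study(
    config: SyntheticStudyConfig | None = None, seed: int | None = None
) -> list[PlotData]:
    """Generate the full 18-plot study (positions, marks, abiotic values).

    ``seed`` overrides ``config.seed``.  Plots are U1..U6, M1..M6, L1..L6 in
    transect order, at increasing distance from the river.
    """
    config = config or SyntheticStudyConfig()
    if seed is not None:
        config = config.with_seed(seed)
    ab = config.abiotic
    # covariate ranges across the study, for the 10%-of-range noise sd
    def _range(offsets, slope):
        vals = [o + slope * d for o in offsets for d in config.distances]
        return max(vals) - min(vals)

    gd_sd = ab.noise_fraction * _range(ab.gd_offsets, ab.gd_slope)
    sm_sd = ab.noise_fraction * _range(ab.sm_offsets, ab.sm_slope)
    sc_sd = ab.noise_fraction * _range(ab.sc_offsets, ab.sc_slope)
    ph_sd = 0.15

    plots: list[PlotData] = []
    prefixes = {"upper": "U", "middle": "M", "lower": "L"}
    plot_index = 0
    for ti, (transect, settings) in enumerate(config.transects.items()):
        for di, distance in enumerate(config.distances):
            # independent, reproducible substream per plot
            sub = np.random.SeedSequence([config.seed, plot_index])
            pos_seed, mark_seed, ab_seed = sub.spawn(3)
            positions = _plot_positions(transect, settings, distance, config.window, pos_seed)
            trees = attach_marks(
                positions, settings.grade_mix, config.allometry, mark_seed,
                dbh_tilts=settings.dbh_tilts,
            )
            arng = np.random.default_rng(ab_seed)
            abiotic = {
                "gd": float(ab.gd_offsets[ti] + ab.gd_slope * distance + arng.normal(0, gd_sd)),
                "sm": float(ab.sm_offsets[ti] + ab.sm_slope * distance + arng.normal(0, sm_sd)),
                "sc": float(ab.sc_offsets[ti] + ab.sc_slope * distance + arng.normal(0, sc_sd)),
                "ph": float(ab.ph_offset + arng.normal(0, ph_sd)),
            }
            plots.append(
                PlotData(
                    plot_id=f"{prefixes[transect]}{di + 1}",
                    transect=transect,
                    distance_from_river=distance,
                    altitude=None,
                    window=config.window,
                    trees=trees,
                    abiotic=abiotic,
                )
            )
            plot_index += 1
    return plots
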