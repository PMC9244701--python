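"""End-to-end orchestration: run every analysis stage over a study and
write the result tables, per-plot function curves, intensity grids and a
reproducibility manifest.

The bundle mirrors the shape of a stand-structure study report:

* ``stand_structure.csv`` — one row per transect (tree count, age-grade
  percentages, SDI, biometric means +- sd, CPA) plus the population-fit
  model, R^2 and trend label;
* ``pattern_indices.csv`` — one row per plot with ANN, DMI, HSI and
  Morisita values, standardised scores and pattern labels, plus the g(r)
  overall label and mean;
* ``transect_g.csv`` — mean g(r) per transect;
* ``correlations.csv`` — Pearson r/p of the chosen index against DR, GD,
  SM, SC and pH;
* ``functions/<plot>.csv`` — r, K, g, envelope and per-r label curves;
* ``intensity/<plot>.csv`` — kernel intensity grids (north-up);
* ``manifest.json`` — parameters, seeds, input hashes and output hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .aggregation_indices import (
    IndexResult,
    ann_index,
    david_moore,
    hopkins_skellam,
    morisita,
    quadrat_counts,
)
from .env_correlation import build_correlation_table
from .intensity_map import kernel_intensity, write_intensity_csv
from .pattern_functions import (
    PatternFunctionResult,
    RGrid,
    csr_envelope,
    summarize_transect_g,
)
from .stand_model import PlotData, write_results
from .structure_metrics import (
    FitError,
    classify_population_trend,
    crown_projection_area,
    dbh_class_histogram,
    fit_population_model,
    stand_summary,
    GRADES,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "AnalysisBundle", "analyze"]

#: decimal places applied to output tables
_TABLE_DECIMALS = {
    "ann": 2, "dmi": 2, "hsi": 2, "morisita": 2,
    "ann_score": 2, "dmi_score": 2, "hsi_score": 2, "morisita_score": 2,
    "g_mean": 2, "mean_g": 2,
    "young_pct": 1, "near_mature_pct": 1, "mature_pct": 1, "old_pct": 1,
    "cpa": 1, "mean_th": 2, "sd_th": 2, "mean_dbh": 2, "sd_dbh": 2,
    "mean_cd": 2, "sd_cd": 2, "r_squared": 3, "r": 3, "p": 4,
}


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the full pipeline."""

    r_max: float = 25.0
    ring_width: float = 1.0
    n_sim: int = 199
    correction: str = "isotropic"
    quadrat_side: float = 10.0
    hsi_samples: int | None = None  # default min(n, 100)
    kernel_radius: float = 5.0
    kernel_cell: float = 1.0
    cpa_cell: float = 0.1
    correlate_index: str = "ann"  # ann | hsi | dmi | morisita | gmean
    seed: int = 42

    def r_grid(self) -> RGrid:
        step = self.ring_width
        return RGrid(
            r=np.arange(step, self.r_max + step / 2, step), ring_width=step
        )


@dataclass
class AnalysisBundle:
    """In-memory results of one pipeline run."""

    stand_structure: pd.DataFrame
    pattern_indices: pd.DataFrame
    transect_g: pd.DataFrame
    correlations: pd.DataFrame
    functions: dict[str, PatternFunctionResult]
    index_results: dict[str, dict[str, IndexResult]]
    trends: dict[str, str]
    manifest: dict = field(default_factory=dict)


def _plot_seed(master: int, plot_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master, 1000 + plot_index])


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze(
    plots: Sequence[PlotData],
    params: AnalysisParams | None = None,
    out_dir: str | Path | None = None,
    input_paths: Mapping[str, str | Path] | None = None,
) -> AnalysisBundle:
    """Run the full analysis over a study.

    When ``out_dir`` is given, all tables, per-plot curves, intensity grids
    and the manifest are written there.  Any stage failure raises with the
    failing plot and stage named.
    """
    params = params or AnalysisParams()
    r_grid = params.r_grid()
    t0 = time.time()

    functions: dict[str, PatternFunctionResult] = {}
    index_results: dict[str, dict[str, IndexResult]] = {}
    intensity = {}
    rows = []
    for pi, plot in enumerate(plots):
        stage = "setup"
        try:
            pts = plot.coords()
            seeds = _plot_seed(params.seed, pi).spawn(4)

            stage = "pattern_functions"
            env = csr_envelope(
                pts, plot.window, r_grid, n_sim=params.n_sim,
                seed=seeds[0], correction=params.correction,
            )
            functions[plot.plot_id] = env

            stage = "aggregation_indices"
            ann = ann_index(pts, plot.window)
            counts = quadrat_counts(pts, plot.window, params.quadrat_side)
            dmi = david_moore(counts, n_sim=params.n_sim, seed=seeds[1])
            mor = morisita(counts, n_sim=params.n_sim, seed=seeds[2])
            hsi = hopkins_skellam(
                pts, plot.window, n_sample=params.hsi_samples,
                seed=seeds[3], n_sim=params.n_sim,
            )
            index_results[plot.plot_id] = {
                "ANN": ann, "DMI": dmi, "HSI": hsi, "Morisita": mor
            }

            stage = "intensity_map"
            intensity[plot.plot_id] = kernel_intensity(
                pts, plot.window, radius=params.kernel_radius, cell=params.kernel_cell
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed on plot {plot.plot_id}: {exc}"
            ) from exc

        rows.append(
            {
                "plot_id": plot.plot_id,
                "transect": plot.transect,
                "n_trees": plot.n,
                "ann": ann.value, "ann_score": ann.score, "ann_label": ann.label,
                "dmi": dmi.value, "dmi_score": dmi.score, "dmi_label": dmi.label,
                "hsi": hsi.value, "hsi_score": hsi.score, "hsi_label": hsi.label,
                "morisita": mor.value, "morisita_score": mor.score,
                "morisita_label": mor.label,
                "g_mean": env.g_mean, "g_label": env.overall_label,
            }
        )
        logger.info("plot %s analysed in %.1fs", plot.plot_id, time.time() - t0)
    pattern_indices = pd.DataFrame(rows)

    # --- per-transect stand structure + population fits -------------------
    struct_rows = []
    trends: dict[str, str] = {}
    for transect in dict.fromkeys(p.transect for p in plots):
        members = [p for p in plots if p.transect == transect]
        pooled = [t for p in members for t in p.trees]
        area_ha = sum(p.window.area_ha for p in members)
        summary = stand_summary(pooled, members[0].window, area_ha=area_ha, cpa_cell=1.0)
        # CPA is per-plot cover averaged over plots (pooling windows would
        # overlay stems from different plots in the same coordinates)
        cpa = float(
            np.mean([
                crown_projection_area(p.trees, p.window, cell=params.cpa_cell)
                for p in members
            ])
        )
        counts, _ = dbh_class_histogram(pooled)
        try:
            fit = fit_population_model(counts)
            model, r2 = fit.model, fit.r_squared
        except FitError:
            model, r2 = None, float("nan")
        trend = classify_population_trend(summary.grade_percentages, model)
        trends[transect] = trend
        struct_rows.append(
            {
                "transect": transect,
                "n_trees": summary.n_trees,
                "young_pct": summary.grade_percentages["young"],
                "near_mature_pct": summary.grade_percentages["near_mature"],
                "mature_pct": summary.grade_percentages["mature"],
                "old_pct": summary.grade_percentages["old"],
                "sdi": round(summary.sdi),
                "mean_th": summary.mean_th, "sd_th": summary.sd_th,
                "mean_dbh": summary.mean_dbh, "sd_dbh": summary.sd_dbh,
                "mean_cd": summary.mean_cd, "sd_cd": summary.sd_cd,
                "cpa": cpa,
                "fit_model": model, "r_squared": r2, "trend": trend,
            }
        )
    stand_structure = pd.DataFrame(struct_rows)

    transect_means = summarize_transect_g(plots, functions)
    transect_g = pd.DataFrame(
        [{"transect": t, "mean_g": v} for t, v in transect_means.items()]
    )

    # --- index vs environment --------------------------------------------
    which = params.correlate_index.lower()
    if which == "gmean":
        index_values = {p.plot_id: functions[p.plot_id].g_mean for p in plots}
        index_name = "g_mean"
    else:
        key = {"ann": "ANN", "hsi": "HSI", "dmi": "DMI", "morisita": "Morisita"}[which]
        index_values = {p.plot_id: index_results[p.plot_id][key].value for p in plots}
        index_name = key
    correlations = build_correlation_table(plots, index_values, index_name)

    bundle = AnalysisBundle(
        stand_structure=stand_structure,
        pattern_indices=pattern_indices,
        transect_g=transect_g,
        correlations=correlations,
        functions=functions,
        index_results=index_results,
        trends=trends,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        tables = {
            "stand_structure": stand_structure,
            "pattern_indices": pattern_indices,
            "transect_g": transect_g,
            "correlations": correlations,
        }
        paths = write_results(tables, out_dir, decimals=_TABLE_DECIMALS)
        fn_dir = out_dir / "functions"
        fn_dir.mkdir(exist_ok=True)
        for plot_id, env in functions.items():
            df = pd.DataFrame(
                {
                    "r": env.r_grid.r,
                    "k_hat": env.k_hat,
                    "g_hat": env.g_hat,
                    "env_lo": env.envelope_lo,
                    "env_hi": env.envelope_hi,
                    "label": list(env.per_r_label),
                }
            )
            df.to_csv(fn_dir / f"{plot_id}.csv", index=False)
        int_dir = out_dir / "intensity"
        for plot_id, imap in intensity.items():
            write_intensity_csv(imap, int_dir / f"{plot_id}.csv")

        manifest = {
            "tool": "standpattern",
            "version": __version__,
            "parameters": asdict(params),
            "inputs": {
                str(k): {"path": str(v), "sha256": _hash_file(Path(v))}
                for k, v in (input_paths or {}).items()
            },
            "outputs": {
                name: {"path": str(p), "sha256": _hash_file(p)}
                for name, p in paths.items()
            },
            "n_plots": len(plots),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        bundle.manifest = manifest
    return bundle
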