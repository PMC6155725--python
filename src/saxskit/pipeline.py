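"""Per-concentration series analysis and reporting.

Orchestrates, for each concentration of a cellulose/ionic-liquid series:
Kratky-peak initialization, composite model fitting, equivalent-sphere
sizing of each aggregate, and the small/large forward-intensity ratio
I2(0)/I1(0).  Components are labelled so subscript 1 is the larger
aggregate (descending rg).  The ratio column is normalized by its maximum
over the series, a package convention recorded in the report itself.

A row whose fit fails is flagged and the series continues.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .fitting import FitResult, fit_composite, initialize_from_kratky
from .models import sphere_diameter
from .profiles import ScatteringProfile

logger = logging.getLogger(__name__)

__all__ = ["SeriesConfig", "SeriesRow", "SeriesReport", "analyze_series",
           "intensity_ratio", "export_report", "load_report", "CSV_COLUMNS"]

CSV_COLUMNS = [
    "concentration",
    "Rg1", "Rg1_sd", "d1", "d1_sd", "s1", "s1_sd",
    "Rg2", "Rg2_sd", "d2", "d2_sd", "s2", "s2_sd",
    "ds", "ds_sd",
    "D_large_nm", "D_small_nm", "I2I1_norm",
]

# Default component layout mirrors the published series: a single aggregate
# below 50 mol %, two aggregates plus a bundle shoulder at 50-80 mol %.
def default_components(concentration: float) -> tuple[int, bool]:
    """(number of GGP components, include Porod shoulder) for a concentration."""
    if concentration >= 50:
        return 2, True
    return 1, False


@dataclass(frozen=True)
class SeriesConfig:
    """Knobs for a series analysis run."""

    components: Mapping[float, tuple[int, bool]] | None = None  # conc -> (n_ggp, shoulder)
    n_starts: int = 5
    seed: int = 0
    fixed: tuple[str, ...] = ()
    bounds: Mapping[str, tuple[float, float]] | None = None
    fit_window: tuple[float, float] | None = None

    def layout_for(self, concentration: float) -> tuple[int, bool]:
        if self.components is not None and concentration in self.components:
            return self.components[concentration]
        return default_components(concentration)


@dataclass
class SeriesRow:
    """One concentration's fitted parameters and derived quantities."""

    concentration: float
    params: dict[str, float] = field(default_factory=dict)   # Table-style values
    stderr: dict[str, float] = field(default_factory=dict)
    diameter_large: float | None = None
    diameter_small: float | None = None
    intensity_ratio: float | None = None       # raw I2(0)/I1(0)
    intensity_ratio_norm: float | None = None  # divided by series maximum
    chi2_reduced: float | None = None
    converged: bool = False
    error: str | None = None
    fit: FitResult | None = None


@dataclass
class SeriesReport:
    rows: list[SeriesRow]
    normalization: str = "I2(0)/I1(0) divided by its maximum over the series"


def intensity_ratio(fit: FitResult) -> float | None:
    """I2(0)/I1(0): forward intensity of the smaller aggregate over that of
    the larger.  None when the fit has fewer than two GGP components."""
    if "i0_2" not in fit.estimates or "i0_1" not in fit.estimates:
        return None
    return fit.estimates["i0_2"] / fit.estimates["i0_1"]


def _row_from_fit(concentration: float, fit: FitResult) -> SeriesRow:
    est, err = fit.estimates, fit.stderr
    params: dict[str, float] = {}
    stderr: dict[str, float] = {}
    mapping = {
        "Rg1": "rg_1", "d1": "d_1", "s1": "s_1",
        "Rg2": "rg_2", "d2": "d_2", "s2": "s_2",
        "ds": "ds",
    }
    for col, key in mapping.items():
        if key in est:
            params[col] = est[key]
            if key in err:
                stderr[col] = err[key]
    row = SeriesRow(
        concentration=concentration,
        params=params,
        stderr=stderr,
        chi2_reduced=fit.chi2_reduced,
        converged=fit.converged,
        fit=fit,
    )
    if "rg_1" in est:
        row.diameter_large = sphere_diameter(est["rg_1"])
    if "rg_2" in est:
        row.diameter_small = sphere_diameter(est["rg_2"])
    row.intensity_ratio = intensity_ratio(fit)
    return row


def analyze_series(
    profiles: Mapping[float, ScatteringProfile],
    config: SeriesConfig | None = None,
) -> SeriesReport:
    """Run initialization -> fit -> sizing -> ratio for every concentration."""
    if not profiles:
        raise ValueError("analyze_series needs at least one profile")
    config = config or SeriesConfig()
    rows: list[SeriesRow] = []
    for conc in sorted(profiles):
        profile = profiles[conc]
        n_ggp, shoulder = config.layout_for(conc)
        try:
            init = initialize_from_kratky(
                profile, n_components=n_ggp, include_shoulder=shoulder
            )
            fit = fit_composite(
                profile,
                init,
                bounds=config.bounds,
                fixed=config.fixed,
                n_starts=config.n_starts,
                seed=config.seed,
            )
            rows.append(_row_from_fit(conc, fit))
        except Exception as exc:
            logger.warning("fit failed at %s mol %%: %s", conc, exc)
            rows.append(SeriesRow(concentration=conc, error=str(exc)))
    ratios = [r.intensity_ratio for r in rows if r.intensity_ratio is not None]
    if ratios:
        peak = max(ratios)
        for r in rows:
            if r.intensity_ratio is not None and peak > 0:
                r.intensity_ratio_norm = r.intensity_ratio / peak
    return SeriesReport(rows=rows)


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "n/a"
    return f"{value:.6g}"


def export_report(report: SeriesReport, path: str | Path, format: str = "csv") -> Path:
    """Write the report as CSV (fixed 18-column table layout, 'n/a' for
    absent values) or JSON (full structure, round-trippable)."""
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for row in report.rows:
                rec = [_fmt(row.concentration)]
                for col in CSV_COLUMNS[1:15]:
                    if col.endswith("_sd"):
                        rec.append(_fmt(row.stderr.get(col[:-3])))
                    else:
                        rec.append(_fmt(row.params.get(col)))
                rec.append(_fmt(row.diameter_large))
                rec.append(_fmt(row.diameter_small))
                rec.append(_fmt(row.intensity_ratio_norm))
                writer.writerow(rec)
    elif format == "json":
        payload = {
            "normalization": report.normalization,
            "rows": [
                {
                    "concentration": row.concentration,
                    "params": row.params,
                    "stderr": row.stderr,
                    "diameter_large": row.diameter_large,
                    "diameter_small": row.diameter_small,
                    "intensity_ratio": row.intensity_ratio,
                    "intensity_ratio_norm": row.intensity_ratio_norm,
                    "chi2_reduced": row.chi2_reduced,
                    "converged": row.converged,
                    "error": row.error,
                }
                for row in report.rows
            ],
        }
        path.write_text(json.dumps(payload, indent=2, default=float))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def load_report(path: str | Path) -> SeriesReport:
    """Read back a JSON report written by :func:`export_report`."""
    payload = json.loads(Path(path).read_text())
    rows = [
        SeriesRow(
            concentration=rec["concentration"],
            params=rec["params"],
            stderr=rec["stderr"],
            diameter_large=rec["diameter_large"],
            diameter_small=rec["diameter_small"],
            intensity_ratio=rec["intensity_ratio"],
            intensity_ratio_norm=rec["intensity_ratio_norm"],
            chi2_reduced=rec["chi2_reduced"],
            converged=rec["converged"],
            error=rec["error"],
        )
        for rec in payload["rows"]
    ]
    return SeriesReport(rows=rows, normalization=payload["normalization"])
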