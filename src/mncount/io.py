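"""Reading and writing plot tables, run configs, and reports.

The canonical interchange format is a UTF-8 CSV with one row per plot and
columns exactly::

    site_id, plot_id, area_km2, elapsed_days, z, x_t1_only, x_t2_only,
    x_both, y, revisited

Structural invariants are enforced on read with row-level messages; in
particular a plot without nest sign on the first survey (z = 0) must carry
zero counts and no revisit — unused plots are never revisited by design.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import PlotObservation, Study

__all__ = ["PLOT_TABLE_COLUMNS", "read_plot_table", "write_plot_table",
           "read_site_areas", "write_site_areas"]

PLOT_TABLE_COLUMNS = [
    "site_id",
    "plot_id",
    "area_km2",
    "elapsed_days",
    "z",
    "x_t1_only",
    "x_t2_only",
    "x_both",
    "y",
    "revisited",
]

_INT_COLUMNS = ["z", "x_t1_only", "x_t2_only", "x_both", "y"]


def write_plot_table(study: Study | list[PlotObservation], path) -> None:
    """Write the plot table CSV ('.' decimal separator, header row)."""
    plots = study.plots if isinstance(study, Study) else study
    rows = [
        {
            "site_id": p.site_id,
            "plot_id": p.plot_id,
            "area_km2": p.area,
            "elapsed_days": p.elapsed_days,
            "z": p.z,
            "x_t1_only": p.x_t1_only,
            "x_t2_only": p.x_t2_only,
            "x_both": p.x_both,
            "y": p.y,
            "revisited": p.revisited,
        }
        for p in plots
    ]
    pd.DataFrame(rows, columns=PLOT_TABLE_COLUMNS).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_plot_table(path) -> Study:
    """Read and validate a plot table; invalid rows raise with their index."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plot table not found: {path}")
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValueError(f"plot table {path} is empty") from None
    if df.empty:
        raise ValueError(f"plot table {path} contains a header but no plots")
    missing = [c for c in PLOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot table {path} is missing columns: {missing}")

    plots: list[PlotObservation] = []
    for idx, row in df.iterrows():
        try:
            for col in _INT_COLUMNS:
                value = row[col]
                if float(value) != int(value):
                    raise ValueError(f"column {col} must be an integer, got {value}")
            revisited = row["revisited"]
            if isinstance(revisited, str):
                revisited = revisited.strip().lower() in ("true", "1", "yes")
            plot = PlotObservation(
                site_id=str(row["site_id"]),
                plot_id=str(row["plot_id"]),
                area=float(row["area_km2"]),
                elapsed_days=float(row["elapsed_days"]),
                z=int(row["z"]),
                x_t1_only=int(row["x_t1_only"]),
                x_t2_only=int(row["x_t2_only"]),
                x_both=int(row["x_both"]),
                y=int(row["y"]),
                revisited=bool(revisited),
            )
            plot.validate()
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"plot table {path}, row {idx}: {exc}") from None
        plots.append(plot)
    return Study(plots=plots)


def read_site_areas(path) -> dict[str, float]:
    """Site areas (km^2) from a JSON or YAML mapping site_id -> area."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or not data:
        raise ValueError(f"{path}: expected a non-empty mapping of site_id -> km^2")
    areas = {str(k): float(v) for k, v in data.items()}
    for k, v in areas.items():
        if not v > 0:
            raise ValueError(f"{path}: area for site {k!r} must be > 0, got {v}")
    return areas


def write_site_areas(areas: dict[str, float], path) -> None:
    Path(path).write_text(json.dumps(areas, indent=1), encoding="utf-8")
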