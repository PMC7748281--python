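"""Reading and writing localization tables and clustering results.

CSV/TSV is the canonical interchange format.  Column headers are detected
for the common dialects ``x, y, z`` and ``x [nm], y [nm], z [nm]``
(ThunderSTORM export style); an explicit column mapping overrides
detection.  Units are nanometres throughout.
"""

from __future__ import annotations

import json
import logging
import re
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ClusterResult, LocalizationTable
from .metrics import hull_radius

__all__ = [
    "read_localizations",
    "write_localizations",
    "write_results",
    "write_provenance",
]

logger = logging.getLogger("focal3d")

_AXIS_PATTERNS = {
    "x": re.compile(r"^x(\s*\[?nm\]?)?$"),
    "y": re.compile(r"^y(\s*\[?nm\]?)?$"),
    "z": re.compile(r"^z(\s*\[?nm\]?)?$"),
}


def _detect_columns(columns) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        norm = str(col).strip().strip('"').lower()
        for axis, pat in _AXIS_PATTERNS.items():
            if axis not in mapping and pat.match(norm):
                mapping[axis] = col
    return mapping


def read_localizations(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> LocalizationTable:
    """Read a delimited localization table.

    ``column_map`` maps ``{"x": <col>, "y": <col>, "z": <col>}`` explicitly;
    otherwise headers are auto-detected.  A file without a z column is
    admitted as 2D: z is set to a constant 0 and flagged in the table's
    extra attributes.  Rows with non-finite coordinates are dropped with a
    logged count; remaining non-coordinate columns are carried through
    untouched.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        logger.warning("empty localization file: %s", path)
        return LocalizationTable(xyz=np.empty((0, 3)))

    mapping = dict(column_map) if column_map else _detect_columns(df.columns)
    missing = [a for a in ("x", "y") if a not in mapping]
    if missing:
        raise ValueError(
            f"could not find columns for axes {missing} in {list(df.columns)}; "
            "pass an explicit column_map"
        )
    is_2d = "z" not in mapping

    x = pd.to_numeric(df[mapping["x"]], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[mapping["y"]], errors="coerce").to_numpy(dtype=float)
    z = (
        np.zeros_like(x)
        if is_2d
        else pd.to_numeric(df[mapping["z"]], errors="coerce").to_numpy(dtype=float)
    )
    xyz = np.column_stack([x, y, z])
    finite = np.all(np.isfinite(xyz), axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.info("dropped %d rows with non-finite coordinates", n_bad)

    used = {mapping[a] for a in mapping}
    extra_cols = [c for c in df.columns if c not in used]
    extra = df.loc[finite, extra_cols].reset_index(drop=True) if extra_cols else None
    if is_2d:
        if extra is None:
            extra = pd.DataFrame(index=range(int(finite.sum())))
        extra = extra.assign(constant_z=True)
    return LocalizationTable(xyz=xyz[finite], extra=extra)


def write_localizations(
    table: LocalizationTable, path: str | Path, labels: np.ndarray | None = None
) -> None:
    """Write a localization table as CSV (columns x, y, z [+ extras]
    [+ cluster_id when ``labels`` is given]), full float precision."""
    df = pd.DataFrame(table.xyz, columns=["x", "y", "z"])
    if table.extra is not None:
        for c in table.extra.columns:
            df[c] = table.extra[c].to_numpy()
    if labels is not None:
        df["cluster_id"] = np.asarray(labels, dtype=np.int64)
    df.to_csv(path, index=False, float_format="%.17g")


def write_results(
    table: LocalizationTable,
    result: ClusterResult,
    path: str | Path,
    summary_path: str | Path | None = None,
) -> tuple[Path, Path]:
    """Write the labeled localization table and a per-cluster summary.

    The labeled CSV is the input table plus an integer ``cluster_id`` column
    (-1 = noise).  The summary CSV has one row per cluster: id, localization
    count, voxel count, centroid and convex-hull effective radius.  The
    summary path defaults to ``<path stem>_clusters.csv``.
    """
    if len(result.labels) != table.n_l:
        raise ValueError("labels length must equal the number of localizations")
    path = Path(path)
    if summary_path is None:
        summary_path = path.with_name(path.stem + "_clusters.csv")
    summary_path = Path(summary_path)

    write_localizations(table, path, labels=result.labels)

    rows = []
    for i, cl in enumerate(result.clusters):
        hr = hull_radius(table.xyz[cl.member_indices])
        rows.append(
            {
                "cluster_id": i,
                "n_localizations": cl.n_localizations,
                "n_voxels": cl.n_voxels,
                "centroid_x": cl.centroid[0],
                "centroid_y": cl.centroid[1],
                "centroid_z": cl.centroid[2],
                "effective_radius": hr.r_eff,
            }
        )
    cols = [
        "cluster_id",
        "n_localizations",
        "n_voxels",
        "centroid_x",
        "centroid_y",
        "centroid_z",
        "effective_radius",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(summary_path, index=False)
    return path, summary_path


def write_provenance(path: str | Path, config: dict) -> Path:
    """Write a machine-readable provenance record (config + seed + software
    version + timestamp) alongside a result file."""
    from . import __version__

    record = {
        "focal3d_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **config,
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return path
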