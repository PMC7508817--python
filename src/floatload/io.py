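"""CSV and raster readers/writers with strict schema validation.

All tables are UTF-8 CSV with ISO-8601 dates and '.' decimal separator;
units are embedded in column names (``q_mean_m3s``, ``tp_ugL``) so a
mis-united file fails loudly instead of silently. Lines starting with
``#`` are comments. Rasters travel as ESRI ASCII grids (plain text), one
fraction layer per file.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_table",
    "write_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "RunManifest",
]


class SchemaError(ValueError):
    """Raised when a CSV fails schema validation."""


# schema: required columns -> whether the column must parse as a number
SCHEMAS: dict[str, dict[str, bool]] = {
    "traits": {"study_id": False, "trait": False, "value": True},
    "concentrations": {"site": False, "date": False, "tp_ugL": True, "tn_ugL": True},
    "vegetation": {"site": False, "date": False, "area_km2": True, "basis": False},
    "cover": {"site": False, "date": False, "cover_km2": True, "sensor": False},
    "gauges": {"station_id": False, "area_km2": True, "q_mean_m3s": True},
    "hydrograph": {"year": True, "month": True, "value": True, "kind": False},
    "reaches": {"site": False, "length_km": True},
    "sites": {"site": False, "q_mean_m3s": True, "veg_area_km2": True},
    "landcover": {"catchment": False, "catchment_area_km2": True},
    "budget": {"site": False, "nutrient": False, "pool_Mg": True, "load_Mg_yr": True},
    "periods": {"label": False, "start_year": True, "end_year": True},
}


def _data_line_numbers(path: Path) -> list[int]:
    """1-based file line numbers of non-comment, non-blank lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                out.append(i)
    return out


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against one of the named schemas.

    Missing required columns and rows whose numeric fields do not parse
    raise :class:`SchemaError` naming the column and the offending file
    line number. Unknown columns are preserved untouched.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {', '.join(missing)}")
    line_nos = _data_line_numbers(path)  # [header, row0, row1, ...]
    for col, numeric in required.items():
        if not numeric:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            lineno = line_nos[row + 1] if row + 1 < len(line_nos) else -1
            raise SchemaError(
                f"{path.name}: malformed value {df[col].iloc[row]!r} in column "
                f"{col!r} at line {lineno}"
            )
        df[col] = parsed
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, comments: list[str] | None = None
) -> None:
    """Write a CSV, optionally preceded by '#' comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, index=False)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (values, cellsize_m).

    NODATA cells become NaN. Only the square-cell single-band dialect is
    supported.
    """
    header: dict[str, float] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines) and lines[i].split() and not _is_number(lines[i].split()[0]):
        key, val = lines[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.loadtxt(_io.StringIO("\n".join(lines[i:])))
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise SchemaError(
            f"{Path(path).name}: grid body {data.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    if "nodata_value" in header:
        data = np.where(data == header["nodata_value"], np.nan, data)
    return data, float(header["cellsize"])


def write_ascii_grid(
    values: np.ndarray, cellsize_m: float, path: str | Path, nodata: float = -9999
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (upper-left origin)."""
    values = np.asarray(values, float)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = np.where(np.isnan(values), nodata, values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {values.shape[1]}\n")
        fh.write(f"nrows {values.shape[0]}\n")
        fh.write("xllcorner 0.0\nyllcorner 0.0\n")
        fh.write(f"cellsize {cellsize_m}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, body, fmt="%.6g")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run.

    Captures enough (input checksums, config hash, seed, version) that a
    rerun with identical inputs can be verified to produce identical
    outputs.
    """

    seed: int | None = None
    version: str = ""
    config_hash: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def set_config(self, config: dict) -> None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        self.config_hash = hashlib.sha256(blob).hexdigest()

    def finalize(self) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
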