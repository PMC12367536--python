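"""Readers/writers for the canonical long-format budget table and run configs.

Interchange format: comma-delimited UTF-8 text, "." decimal, header row

    region_id,country,year,member_id,sector,variable,value

with ``variable`` one of in_fert, in_man, in_dep, in_bnf, out_crops,
out_past, ag_area, nonag_area.  Output tables written by this package
carry a leading ``#`` comment line with the package version and the
run-config hash, which all readers here skip.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .budget import AREA_COLUMNS, COMPONENTS, KEY_COLUMNS, SECTORS

logger = logging.getLogger(__name__)

VARIABLES = tuple(COMPONENTS + AREA_COLUMNS)
YEAR_RANGE = (1850, 2030)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    input_table: str = ""
    output_dir: str = "out"
    seed: int = 0
    n_regions: int = 393
    baseline_window: tuple[int, int] = (2015, 2019)
    som_epochs: int = 500
    som_radius: tuple[float, float] = (1.0, 0.1)
    som_learning_rate: tuple[float, float] = (0.5, 0.01)
    grid_step: float = 0.01
    tmp_modes: tuple[str, ...] = ("same", "improved")
    scopes: tuple[str, ...] = ("typology", "EU27")
    log_level: str = "INFO"

    def hash(self) -> str:
        # scientific parameters only: two runs of the same analysis hash
        # identically regardless of where their files live
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("input_table", "output_dir", "log_level")}
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("baseline_window", "som_radius", "som_learning_rate",
                    "tmp_modes", "scopes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _header_line(config: RunConfig | None) -> str:
    h = config.hash() if config is not None else "none"
    return f"# nsurplus={__version__} config={h}\n"


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """Write any result table with the provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_line(config))
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_budget_table(
    records: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write wide component records as the canonical long-format table."""
    long = records.melt(
        id_vars=KEY_COLUMNS, value_vars=list(VARIABLES),
        var_name="variable", value_name="value",
    )
    write_table(long, path, config)


def read_budget_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a canonical long-format table into wide records.

    Schema violations (unknown variable, out-of-range year or member,
    non-numeric value, duplicate key) raise with the offending row
    numbers of the source file.
    """
    path = Path(path)
    long = pd.read_csv(path, comment="#", dtype={"value": str})
    required = set(KEY_COLUMNS + ["variable", "value"])
    if set(long.columns) != required:
        raise ValueError(
            f"bad header: expected columns {sorted(required)}, got {sorted(long.columns)}"
        )
    # row numbers in the source file (1-based, counting header and comment)
    offset = 2
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            offset = 3
    rows = long.index + offset

    def offenders(mask, what):
        if mask.any():
            where = list(rows[mask][:10])
            raise ValueError(f"{what} at rows {where}")

    offenders(~long["variable"].isin(VARIABLES), "unknown variable name")
    value = pd.to_numeric(long["value"], errors="coerce")
    offenders(value.isna() & long["value"].notna(), "non-numeric value")
    offenders(long["value"].isna(), "missing value")
    long["value"] = value
    offenders(
        (long["year"] < YEAR_RANGE[0]) | (long["year"] > YEAR_RANGE[1]),
        f"year outside {YEAR_RANGE}",
    )
    offenders(~long["member_id"].between(1, 16), "member_id outside 1..16")
    offenders(~long["sector"].isin(SECTORS), "unknown sector")
    dup = long.duplicated(subset=KEY_COLUMNS + ["variable"], keep=False)
    offenders(dup & ~long.duplicated(subset=KEY_COLUMNS + ["variable"], keep="first"),
              "duplicate key")

    wide = long.pivot_table(
        index=KEY_COLUMNS, columns="variable", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    missing = [v for v in VARIABLES if v not in wide.columns]
    if missing:
        raise ValueError(f"table lacks variables: {missing}")
    if wide[list(VARIABLES)].isna().any().any():
        bad = wide.loc[wide[list(VARIABLES)].isna().any(axis=1), KEY_COLUMNS]
        raise ValueError(f"incomplete records:\n{bad.head(10)}")
    return wide[KEY_COLUMNS + list(VARIABLES)]


def write_truth_labels(truth: pd.Series, path: str | Path,
                       config: RunConfig | None = None) -> None:
    df = truth.rename("label").rename_axis("region_id").reset_index()
    write_table(df, path, config)


def read_zenodo_sheet(
    path: str | Path,
    sheet_name: str | int = 0,
) -> pd.DataFrame:
    """Converter stub for the archived-spreadsheet layout.

    Expects a worksheet whose rows carry the canonical long-format columns
    (region_id, country, year, member_id, sector, variable, value) and
    returns them as validated canonical rows, one per input row.
    Spreadsheets are an ingestion convenience only — the delimited text
    format is the core path; assembling rows into complete wide records is
    :func:`read_budget_table`'s job.
    """
    sheet = pd.read_excel(path, sheet_name=sheet_name)
    missing = set(KEY_COLUMNS + ["variable", "value"]) - set(sheet.columns)
    if missing:
        raise ValueError(f"spreadsheet lacks columns: {sorted(missing)}")
    long = sheet[KEY_COLUMNS + ["variable", "value"]].copy()
    bad_var = ~long["variable"].isin(VARIABLES)
    if bad_var.any():
        raise ValueError(f"unknown variable names at sheet rows {list(long.index[bad_var][:10])}")
    value = pd.to_numeric(long["value"], errors="coerce")
    if value.isna().any():
        raise ValueError(f"non-numeric values at sheet rows {list(long.index[value.isna()][:10])}")
    long["value"] = value
    bad_year = (long["year"] < YEAR_RANGE[0]) | (long["year"] > YEAR_RANGE[1])
    if bad_year.any():
        raise ValueError(f"year outside {YEAR_RANGE} at sheet rows {list(long.index[bad_year][:10])}")
    return long


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Log to stderr and optionally a run-local file; idempotent."""
    root = logging.getLogger("nsurplus")
    root.setLevel(level.upper())
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    root.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        root.addHandler(fh)
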