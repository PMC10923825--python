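"""Reading, validation and writing of the delimited input/output tables.

Four input table types are supported: long-format community abundances
(site, year, species, abundance), site metadata with closed factor levels,
per-site annual temperature series, and occurrence-temperature records.
All downstream modules consume the validated pandas DataFrames returned
here; column-name mapping and the delimiter live in a YAML config rather
than positional order, because long-running monitoring programmes rarely
share headers.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

log = logging.getLogger("ctitrack")

BIOLOGICAL_GROUPS = (
    "CHB benthos",
    "CSB benthos",
    "zooplankton",
    "demersal crustaceans",
    "cephalopods",
    "fish",
)
HABITATS = ("benthic/demersal", "estuarine", "pelagic")
REGIONS = ("Baltic", "Mediterranean", "NE Atlantic")
BASIN_TYPES = ("non-enclosed", "semi-enclosed")

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "biological_group": BIOLOGICAL_GROUPS,
    "habitat": HABITATS,
    "region": REGIONS,
    "basin_type": BASIN_TYPES,
}

#: floats are written with 12 significant digits so that write -> read is
#: the identity at the declared precision
FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """A required column is missing or the header cannot be interpreted."""


class ValidationError(ValueError):
    """Rows violate a value-level contract (negative abundance, bad enum...)."""


class ReferentialIntegrityError(ValueError):
    """A site referenced by one table is missing from another."""


DEFAULT_CONFIG: dict = {
    "delimiter": ",",
    "columns": {
        "abundance": {
            "site_id": "site_id",
            "year": "year",
            "species_id": "species_id",
            "abundance": "abundance",
            "replicate": "replicate",
        },
        "metadata": {
            "site_id": "site_id",
            "biological_group": "biological_group",
            "habitat": "habitat",
            "region": "region",
            "basin_type": "basin_type",
        },
        "temperature": {"site_id": "site_id", "year": "year", "sst": "sst",
                        "st100m": "st100m"},
        "occurrence": {"species_id": "species_id", "temperature": "temperature"},
    },
    # duplicate (site, year, species) rows: "error" | "sum"
    "duplicates": "error",
    # sub-annual replicates, if a "replicate" column is present, are reduced
    # to one annual value per (site, year, species) with this reducer
    "annual_reducer": "mean",
}


def load_config(path: str | Path | None = None) -> dict:
    """Load the YAML run configuration, merged over the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                for k2, v2 in val.items():
                    if isinstance(v2, dict) and isinstance(cfg[key].get(k2), dict):
                        cfg[key][k2].update(v2)
                    else:
                        cfg[key][k2] = v2
            else:
                cfg[key] = val
    return cfg


def _read_mapped(path, table: str, config: Mapping) -> pd.DataFrame:
    mapping = config["columns"][table]
    df = pd.read_csv(path, sep=config.get("delimiter", ","))
    hard_missing = [v for k, v in mapping.items()
                    if v not in df.columns and k not in _OPTIONAL.get(table, ())]
    if hard_missing:
        raise SchemaError(
            f"{table} table {path}: missing required column(s) {hard_missing}; "
            f"found {list(df.columns)}"
        )
    rename = {v: k for k, v in mapping.items() if v in df.columns}
    return df.rename(columns=rename)


_OPTIONAL = {
    "abundance": ("replicate",),
    "temperature": ("st100m",),
    "occurrence": ("lat", "lon", "year"),
}


def read_abundance_table(path: str | Path, config: Mapping | None = None) -> pd.DataFrame:
    """Read and validate a long-format community abundance table.

    Returns a DataFrame with columns ``site_id, year, species_id, abundance``.
    Duplicate (site, year, species) keys are an error unless
    ``config["duplicates"] == "sum"``; rows with missing or negative abundance
    are rejected with their (0-based data) row numbers.
    """
    config = config or DEFAULT_CONFIG
    df = _read_mapped(path, "abundance", config)
    if "replicate" in df.columns:
        # sub-annual replicates reduced to one annual value per species;
        # the unit of analysis downstream is the calendar year
        reducer = config.get("annual_reducer", "mean")
        df = (df.groupby(["site_id", "year", "species_id"], as_index=False)
                ["abundance"].agg(reducer))
        log.info("reduced sub-annual replicates with '%s'", reducer)
    df = df[["site_id", "year", "species_id", "abundance"]].copy()

    bad_na = df.index[df["abundance"].isna()].tolist()
    if bad_na:
        raise ValidationError(f"missing abundance in row(s) {bad_na}")
    df["abundance"] = pd.to_numeric(df["abundance"])
    neg = df.index[df["abundance"] < 0].tolist()
    if neg:
        raise ValidationError(
            f"negative abundance in row(s) {neg}: "
            f"{df.loc[neg, 'abundance'].tolist()}"
        )
    df["year"] = df["year"].astype(int)

    key = ["site_id", "year", "species_id"]
    if df.duplicated(key).any():
        if config.get("duplicates") == "sum":
            df = df.groupby(key, as_index=False)["abundance"].sum()
        else:
            dups = df[df.duplicated(key, keep=False)].sort_values(key)
            raise ValidationError(
                f"duplicate (site, year, species) keys:\n{dups.to_string()}"
            )

    year_counts = df.groupby("site_id")["year"].nunique()
    short = year_counts[year_counts < 2]
    if not short.empty:
        raise ValidationError(
            f"site(s) with fewer than 2 distinct years: {short.index.tolist()}"
        )
    return df.reset_index(drop=True)


def read_metadata_table(path: str | Path, config: Mapping | None = None) -> pd.DataFrame:
    """Read site metadata and validate the closed factor levels."""
    config = config or DEFAULT_CONFIG
    df = _read_mapped(path, "metadata", config)
    df = df[["site_id"] + list(FACTOR_LEVELS)].copy()
    for col, levels in FACTOR_LEVELS.items():
        bad = sorted(set(df[col]) - set(levels))
        if bad:
            raise ValidationError(
                f"unknown {col} level(s) {bad}; allowed: {list(levels)}"
            )
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValidationError(f"duplicated site_id in metadata: {dups}")
    return df.reset_index(drop=True)


def read_temperature_table(path: str | Path, config: Mapping | None = None) -> pd.DataFrame:
    """Read per-site annual temperature series (SST, optional 0-100 m mean)."""
    config = config or DEFAULT_CONFIG
    df = _read_mapped(path, "temperature", config)
    cols = ["site_id", "year", "sst"] + (["st100m"] if "st100m" in df.columns else [])
    df = df[cols].copy()
    df["year"] = df["year"].astype(int)
    if df.duplicated(["site_id", "year"]).any():
        raise ValidationError("temperature table has duplicate (site_id, year) rows")
    return df.reset_index(drop=True)


def read_occurrence_table(path: str | Path, config: Mapping | None = None) -> pd.DataFrame:
    """Read species occurrence-temperature records."""
    config = config or DEFAULT_CONFIG
    df = _read_mapped(path, "occurrence", config)
    if df["temperature"].isna().any() or not pd.api.types.is_numeric_dtype(df["temperature"]):
        df["temperature"] = pd.to_numeric(df["temperature"], errors="raise")
    if df["temperature"].isna().any():
        raise ValidationError("occurrence table has missing temperatures")
    return df.reset_index(drop=True)


def validate_links(abundance: pd.DataFrame, metadata: pd.DataFrame,
                   temperature: pd.DataFrame | None = None) -> None:
    """Check referential integrity between loaded tables.

    Every abundance site must resolve to exactly one metadata row and, when
    temperature analyses are requested, at least one temperature row.
    """
    ab_sites = set(abundance["site_id"])
    missing = sorted(ab_sites - set(metadata["site_id"]))
    if missing:
        raise ReferentialIntegrityError(f"site(s) without metadata: {missing}")
    if temperature is not None:
        no_temp = sorted(ab_sites - set(temperature["site_id"]))
        if no_temp:
            raise ReferentialIntegrityError(
                f"site(s) without temperature series: {no_temp}"
            )


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  delimiter: str = ",") -> dict[str, Path]:
    """Write one tidy delimited file per result table.

    Column order and float formatting (12 significant digits) are stable, so
    writing the same table twice produces byte-identical files and re-reading
    reproduces text columns exactly and reals to the declared precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        dest = out_dir / f"{name}.csv"
        df.to_csv(dest, sep=delimiter, index=False, float_format=FLOAT_FORMAT)
        written[name] = dest
        log.info("wrote %s (%d rows)", dest, len(df))
    return written


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
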