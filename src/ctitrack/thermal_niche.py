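"""Species thermal-preference estimation from occurrence-temperature records.

A species' thermal preference (T_s) is the midpoint between the 5th and 95th
percentiles of the temperatures observed at its occurrence records — a robust
central-tendency summary of its realized thermal distribution. Percentiles use
linear interpolation between closest order statistics (Hyndman-Fan type 7,
numpy's default), fixed so that midpoints are reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("ctitrack")

#: occurrence-count floor below which a percentile pair is considered degenerate
MIN_RECORDS_DEFAULT = 20


class InsufficientDataError(ValueError):
    """Too few occurrence records to estimate a thermal preference."""


@dataclass(frozen=True)
class ThermalPreference:
    species_id: str
    midpoint: float  # °C, (p5 + p95) / 2
    p5: float
    p95: float
    n_records: int


def dedupe_occurrences(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact-duplicate occurrence rows (all fields equal) to one.

    The result is order-independent: rows are sorted on all columns.
    """
    if records.empty:
        return records.copy()
    out = records.drop_duplicates()
    return out.sort_values(list(out.columns), kind="mergesort").reset_index(drop=True)


def estimate_thermal_preference(
    records: pd.DataFrame,
    species_id: str,
    min_records: int = MIN_RECORDS_DEFAULT,
) -> ThermalPreference:
    """Estimate one species' thermal preference.

    Parameters
    ----------
    records
        Occurrence table with at least ``species_id`` and ``temperature``
        columns; deduplicated before estimation.
    species_id
        Species to estimate.
    min_records
        Minimum number of (deduplicated) records required.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_records`` records remain after deduplication.
    """
    sub = dedupe_occurrences(records.loc[records["species_id"] == species_id])
    temps = np.asarray(sub["temperature"], dtype=float)
    if not np.all(np.isfinite(temps)):
        raise ValueError(f"non-finite temperatures for {species_id!r}")
    if temps.size < min_records:
        raise InsufficientDataError(
            f"{species_id!r}: {temps.size} records < min_records={min_records}"
        )
    p5, p95 = np.percentile(temps, [5.0, 95.0])  # linear interpolation (type 7)
    return ThermalPreference(
        species_id=species_id,
        midpoint=(p5 + p95) / 2.0,
        p5=float(p5),
        p95=float(p95),
        n_records=int(temps.size),
    )


def estimate_all_preferences(
    records: pd.DataFrame, min_records: int = MIN_RECORDS_DEFAULT
) -> pd.DataFrame:
    """Estimate preferences for every species in an occurrence table.

    Species with fewer than ``min_records`` deduplicated records are flagged
    insufficient-data, excluded from the result, and logged — downstream CTI
    computation then drops them from the community with a counted warning.
    """
    rows, skipped = [], []
    for sp in sorted(records["species_id"].unique()):
        try:
            pref = estimate_thermal_preference(records, sp, min_records)
        except InsufficientDataError:
            skipped.append(sp)
            continue
        rows.append(pref.__dict__)
    if skipped:
        log.warning("insufficient occurrence data for %d species: %s",
                    len(skipped), skipped[:10])
    return pd.DataFrame(rows, columns=["species_id", "midpoint", "p5", "p95",
                                       "n_records"])
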