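"""Community Temperature Index (CTI) per site and year.

CTI summarises the mean thermal affinity of a community: each species'
thermal preference T_s weighted by w_s = log(A_s + 1), with A_s its relative
abundance (abundance over the community total). Two variants are exposed:

``normalized`` (default)
    CTI = Σ T_s w_s / Σ w_s — a weighted average in °C, bounded by the
    species preferences and invariant to the logarithm base (a base change
    rescales every weight by the same constant, which cancels).
``literal``
    CTI = Σ T_s w_s with no denominator. This is not an average: a
    monoculture's CTI is T · log(2) rather than T, and the value depends on
    the log base. It is retained behind this flag for auditability only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("ctitrack")


class DegenerateSampleError(ValueError):
    """Community with no positive abundance, or no species with a preference."""


@dataclass(frozen=True)
class CTIValue:
    site_id: str
    year: int
    cti: float  # °C
    n_species_used: int
    n_species_dropped: int  # present but lacking a thermal preference
    variant: str


def relative_abundance(composition: Mapping[str, float]) -> dict[str, float]:
    """Abundances divided by the community total; proportions sum to 1."""
    total = float(sum(composition.values()))
    if total <= 0:
        raise DegenerateSampleError("all-zero composition")
    if any(a < 0 for a in composition.values()):
        raise ValueError("negative abundance")
    return {sp: a / total for sp, a in composition.items()}


def compute_cti(
    composition: Mapping[str, float],
    preferences: Mapping[str, float],
    variant: str = "normalized",
    log_base: float = math.e,
    site_id: str = "",
    year: int = 0,
) -> CTIValue:
    """CTI of one community sample.

    ``preferences`` maps species_id -> thermal midpoint (°C). Species present
    in the community but lacking a preference are dropped and counted in
    ``n_species_dropped`` (never imputed).
    """
    if variant not in ("normalized", "literal"):
        raise ValueError(f"unknown variant {variant!r}")
    rel = relative_abundance(composition)
    used = {sp: p for sp, p in rel.items() if p > 0 and sp in preferences}
    n_dropped = sum(1 for sp, p in rel.items() if p > 0 and sp not in preferences)
    if not used:
        raise DegenerateSampleError(
            f"no species with both abundance > 0 and a thermal preference "
            f"(site={site_id!r}, year={year})"
        )
    if n_dropped:
        log.debug("site=%s year=%s: dropped %d species without preferences",
                  site_id, year, n_dropped)
    t = np.array([preferences[sp] for sp in used])
    w = np.log1p(np.array(list(used.values()))) / math.log(log_base)
    if variant == "normalized":
        cti = float(np.dot(t, w) / w.sum())
    else:
        cti = float(np.dot(t, w))
    return CTIValue(site_id=site_id, year=int(year), cti=cti,
                    n_species_used=len(used), n_species_dropped=n_dropped,
                    variant=variant)


def cti_time_series(
    abundance: pd.DataFrame,
    preferences: pd.DataFrame,
    variant: str = "normalized",
    log_base: float = math.e,
) -> pd.DataFrame:
    """CTI for every (site, year) in a long-format abundance table.

    ``preferences`` is the ``estimate_all_preferences`` output (or any frame
    with ``species_id`` and ``midpoint``). Site-years where no species
    resolves to a preference are skipped with a logged warning.
    """
    pref_map = dict(zip(preferences["species_id"], preferences["midpoint"]))
    rows = []
    for (site, year), grp in abundance.groupby(["site_id", "year"], sort=True):
        comp = dict(zip(grp["species_id"], grp["abundance"]))
        try:
            val = compute_cti(comp, pref_map, variant=variant,
                              log_base=log_base, site_id=site, year=year)
        except DegenerateSampleError as err:
            log.warning("skipping site-year: %s", err)
            continue
        rows.append(val.__dict__)
    return pd.DataFrame(rows, columns=["site_id", "year", "cti",
                                       "n_species_used", "n_species_dropped",
                                       "variant"])
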