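#!/usr/bin/env python
"""Warming and CTI trends across the synthetic survey network.

Simulates the 18-station synthetic survey (three regions, six biological
groups; semi-enclosed basins warming faster than the open Atlantic), then
estimates per-site CTI rates (AR(1)-aware GLS), the pooled mixed-model CTI
and SST trends, and the CTI-temperature coupling.

Writes: results/survey_site_trends.csv, results/survey_cti.csv,
results/survey_metadata.csv
"""

from pathlib import Path

import ctitrack as ct
from ctitrack import studies

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    survey = studies.synthetic_survey(seed=seed)
    head = survey["headline"]

    ct.io.write_results({
        "survey_site_trends": survey["site_trends"].drop(columns=["phi"]).assign(
            phi=[p if p is not None else float("nan")
                 for p in survey["site_trends"]["phi"]]),
        "survey_cti": survey["cti"],
        "survey_metadata": survey["metadata"],
    }, OUT)

    pooled_cti = survey["pooled_cti"].fixed_effects["year"]
    pooled_sst = survey["pooled_sst"].fixed_effects["year"]
    rel = survey["cti_vs_sst"].fixed_effects["sst"]
    print(f"sites simulated:                 {head['n_sites']}")
    print(f"SST trend (pooled mixed model):  {10 * pooled_sst[0]:+.3f} °C/decade"
          f"  (t = {pooled_sst[2]:.2f})")
    print(f"CTI trend (pooled mixed model):  {10 * pooled_cti[0]:+.3f} °C/decade"
          f"  (t = {pooled_cti[2]:.2f})")
    print(f"sites with positive CTI_r:       {head['pct_sites_cti_positive']:.1f} %")
    print(f"  ... significantly positive:    "
          f"{head['pct_sites_cti_significantly_positive']:.1f} %")
    print(f"CTI ~ SST slope across sites:    {rel[0]:.3f}  (t = {rel[2]:.2f})")
    print("Communities track the imposed warming: the pooled CTI rate sits "
          "near the pooled SST rate, and per-site rates are almost all "
          "positive.")


if __name__ == "__main__":
    main()
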