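#!/usr/bin/env python
"""CTI rates compared across biological groups, habitats, regions and basins.

Fits mixed models with a year-by-factor interaction for each survey factor
(per-level slopes with two-sided Wald tests) and ranks all factor
combinations by AICc.

Writes: results/survey_factor_trends.csv, results/survey_model_ranking.csv
"""

from pathlib import Path

import ctitrack as ct
from ctitrack import studies

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    survey = studies.synthetic_survey(seed=seed)

    ct.io.write_results({
        "survey_factor_trends": survey["factor_trends"],
        "survey_model_ranking": survey["model_ranking"],
    }, OUT)

    print("per-level CTI_r (°C/yr), two-sided Wald tests:")
    for _, row in survey["factor_trends"].iterrows():
        flag = " (low replication)" if row["low_replication"] else ""
        print(f"  {row['factor']:>17s} | {row['level']:<20s} "
              f"slope {row['slope']:+.4f} ± {row['se']:.4f}  "
              f"p = {row['p_value']:.3g}{flag}")
    best = survey["model_ranking"].iloc[0]
    print(f"\nbest factor combination by AICc: {best['factors']} "
          f"(AICc = {best['aicc']:.1f})")
    print("The factors that actually drive the simulation (region / basin "
          "type, which set the warming rate and connectivity) should rank "
          "ahead of the uninformative ones.")


if __name__ == "__main__":
    main()
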