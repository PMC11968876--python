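"""Intersect kelp habitat with MPAs and account protection by region.

Runs the nested/hierarchical intersection (spatial-join prefilter, exact
polygon intersection per jurisdiction), attributes doubly-covered area to
the highest protection tier, and summarises hectares and percentages per
country, realm, ecoregion and globally, with 10%/30% representation
flags, under results/study/protection/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import setup_logging, study_config

import pandas as pd

from kelpmhw.pipeline import run_pipeline


def main() -> None:
    setup_logging()
    out = run_pipeline(study_config(), ["protection"])
    summary = pd.read_csv(out / "protection" / "protection_summary.csv")
    glob = summary[summary.region_level == "global"].iloc[0]
    print(f"global kelp extent {glob['total_kelp_ha']:.2f} ha; protected "
          f"{100 - glob['pct_unprotected']:.1f}% "
          f"(high {glob['pct_high']:.1f}%, moderate {glob['pct_moderate']:.1f}%, "
          f"less {glob['pct_less']:.1f}%)")
    eco = summary[summary.region_level == "ecoregion"]
    print(f"{int(eco['meets_10'].sum())}/{len(eco)} ecoregions meet the 10% "
          f"effective-protection target; {int(eco['meets_30'].sum())} meet 30%")


if __name__ == "__main__":
    main()
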