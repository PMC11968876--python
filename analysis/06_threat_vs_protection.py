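"""Join projected heatwave threat with protection status per ecoregion.

Mid-term (2041-2060) SSP2-4.5 mean exposure against the percent of kelp
highly (and highly + moderately) protected, one row per ecoregion;
ecoregions with >= 30% effective protection and below-median exposure
are flagged as refugium candidates. Writes
results/study/threat_vs_protection.csv and the run manifest.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import setup_logging, study_config

import pandas as pd

from kelpmhw.pipeline import run_pipeline


def main() -> None:
    setup_logging()
    out = run_pipeline(study_config(), ["report"])
    joined = pd.read_csv(out / "threat_vs_protection.csv")
    print("ecoregions by threat (mid-term SSP2-4.5), least-protected first:")
    cols = ["region_id", "mhw_exposure", "pct_high", "pct_high_moderate"]
    print(joined[cols].round(2).to_string(index=False))
    refugia = joined[joined["refugium_candidate"]]
    if len(refugia):
        print(f"refugium candidates: {', '.join(refugia['region_id'])}")
    else:
        print("no ecoregion currently combines >=30% effective protection "
              "with below-median exposure")


if __name__ == "__main__":
    main()
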