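#!/usr/bin/env python
"""Measurement-error recovery and K-band coverage on synthetic data.

Checks that the estimators recover the generator's truth: the pooled
deviation-rate SD estimated from ~1000 synthetic GB reading sets (4
dosemeters each, 2.0% multiplicative noise, 0.01 mSv rounding, reference
kermas ~0.9-2.4 mGy) should land on 2.0%, and the share of individual
log-responses inside the +/-1.96 SD band that defines the uncertainty
factor K should be ~95%. Writes error_recovery.csv under results/.
"""

import warnings
from pathlib import Path

import pandas as pd

warnings.filterwarnings("ignore", message=".*inconsistent with 11 rotations.*")

from doseresp.response import deviation_rate_sd
from doseresp.synthetic_data import GeneratorConfig, recovery_study, replicate_reading_sets

SEED = 20260920
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for dtype, sd_true in (("EPD", 1.1), ("GB", 2.0), ("LB", 3.5)):
        sets = replicate_reading_sets(dtype, 1000, seed=SEED, error_sd_pct=sd_true)
        est = deviation_rate_sd(sets)[dtype]
        study = recovery_study(GeneratorConfig(seed=SEED), n_replicates=60, dosemeter_type=dtype)
        rows.append({"dosemeter_type": dtype, "sd_true_pct": sd_true,
                     "sd_estimated_pct": round(est, 3),
                     "bias_pct": round(est - sd_true, 3),
                     "k_interval_coverage": round(study["k_interval_coverage"], 3)})
        print(f"{dtype}: generated at {sd_true}%, recovered {est:.2f}% "
              f"(bias {est - sd_true:+.2f}); K-band coverage "
              f"{study['k_interval_coverage']:.1%}")
    pd.DataFrame(rows).to_csv(OUT / "error_recovery.csv", index=False)
    print(f"wrote {OUT / 'error_recovery.csv'}")
    print("note: the EPD estimate sits slightly above 1.1% because the 0.01 mSv "
          "display rounding contributes extra spread at ~1 mGy reference kermas")


if __name__ == "__main__":
    main()
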