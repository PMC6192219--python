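#!/usr/bin/env python
"""Stage 3 — predict DNAm age under every condition.

Applies both clocks (pan-tissue style with gold-standard calibration, blood
style without) to each preprocessed beta matrix and assembles the long
age-estimate table, reporting the correlation with chronological age per
condition.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from epiclockbench import io as eio
from epiclockbench.clock import predict_dnam_age
from epiclockbench.preprocessing import PREPROCESSORS

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clocks = {
        "pan_tissue": (eio.load_clock(ROOT / "data" / "ground_truth" / "clock_pan_tissue.csv"), True),
        "blood": (eio.load_clock(ROOT / "data" / "ground_truth" / "clock_blood.csv"), False),
    }
    rows = []
    for platform in ("A", "B"):
        sheet = eio.load_sample_sheet(ROOT / "data" / f"sample_sheet_{platform}.csv")
        ages = sheet.ages()
        for method in PREPROCESSORS:
            beta = eio.load_beta(ROOT / "betas" / f"beta_{platform}_{method}.tsv")
            for label, (clock, calibrate) in clocks.items():
                pred = predict_dnam_age(beta, clock, calibrate=calibrate)
                r = stats.pearsonr(pred["dnam_age"],
                                   ages.loc[pred.index]).statistic
                print(f"{platform}/{method:8s}/{label:10s}: "
                      f"r(DNAm age, age) = {r:.3f}  (n={len(pred)})")
                for sample_id, rec in pred.iterrows():
                    rows.append({
                        "sample_id": sample_id, "platform": platform,
                        "preprocessing": method, "clock": clock.name,
                        "dnam_age": float(rec["dnam_age"]),
                        "chronological_age": float(ages[sample_id]),
                        "n_imputed": int(rec["n_imputed"]),
                        "calibrated": bool(rec["calibrated"]),
                    })
    out = ROOT / "age_estimates.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {len(rows)} estimates to {out}")


if __name__ == "__main__":
    main()
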