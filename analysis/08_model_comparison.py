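"""AICc model comparison: what predicts home-range size, and what
predicts predictability?

Enumerates linear mixed models (random intercept per individual) over
standardized predictors, ranks them by AICc, and reports full
model-averaged coefficients with unconditional SEs for (a) log
home-range area and (b) rIIV.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from owlmove import modelsel

OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    hr = pd.read_csv(OUT / "homerange.csv")
    summary = pd.read_csv(OUT / "indices_summary.csv")
    riiv = pd.read_csv(OUT / "riiv.csv")
    merged = hr.merge(summary, on=["individual", "period", "period_year"]) \
               .merge(riiv[["individual", "riiv_km"]], on="individual")
    merged["log_hr"] = np.log(merged["area_km2"])
    numeric = [c for c in ["mean_max_disp_km", "riiv_km", "n_nights", "density"]
               if merged[c].nunique() > 1]
    merged, _ = modelsel.standardize(merged, numeric)
    core = [c for c in ["mean_max_disp_km", "riiv_km", "n_nights", "period"]
            if merged[c].nunique() > 1]
    stage2 = [c for c in ["density"] if c in numeric]
    models = modelsel.enumerate_and_rank(merged, "log_hr", core, stage2=stage2)
    modelsel.models_table(models).to_csv(OUT / "models_loghr.csv", index=False)
    avg = modelsel.model_average(models)
    avg.to_csv(OUT / "avg_loghr.csv", index=False)
    print("log(HR) model averaging (delta AICc < 4):")
    print(avg.to_string(index=False))

    # what drives predictability: rIIV against age/sex/tracking effort
    if merged["age_class"].nunique() > 1 and len(merged) >= 8:
        m2 = modelsel.enumerate_and_rank(
            merged, "riiv_km",
            [c for c in ["age_class", "sex", "n_nights"] if merged[c].nunique() > 1],
        )
        modelsel.models_table(m2).to_csv(OUT / "models_riiv.csv", index=False)
        avg2 = modelsel.model_average(m2)
        avg2.to_csv(OUT / "avg_riiv.csv", index=False)
        print("\nrIIV model averaging:")
        print(avg2.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
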