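"""Quality-filter the raw fixes and segment them into retained nights.

Applies the accuracy filter (STD > 50 m), the 15 m/s forward-sweep speed
filter, the 17:00-06:00 night window, period labels, and the inclusion
rules (> 1000 fixes per night, >= 25 nights per individual-period), and
writes the retained night dataset and a QC report under ``results/``.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from owlmove import preprocess

COHORT = Path("scratch/cohort")
OUT = Path("results")
SCRATCH = Path("scratch")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    raw = preprocess.read_fixes(COHORT / "fixes.csv")
    meta = pd.read_csv(COHORT / "meta.csv")
    meta["hatch_date"] = pd.to_datetime(meta["hatch_date"]).dt.date
    nights, rep = preprocess.preprocess(raw, meta)
    SCRATCH.mkdir(exist_ok=True)
    nights.to_csv(SCRATCH / "nights.csv", index=False)
    with open(OUT / "qc.json", "w") as fh:
        json.dump(rep.to_dict(), fh, indent=1)
    print(f"input fixes: {rep.n_input_fixes}")
    print(f"removed by accuracy filter: {rep.removed_std}, by speed filter: {rep.removed_speed}")
    print(f"nights retained: {rep.nights_output}/{rep.nights_input} "
          f"({rep.cells_below_min_nights} individual-period cells dropped)")


if __name__ == "__main__":
    sys.exit(main())
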