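"""Repeatability (Rp) and CVi of nightly max-displacement, and the
across-period consistency of rIIV.

Rp partitions trait variance into among- vs within-individual shares;
CVi standardizes the among-individual SD by the trait mean.  The same
machinery applied to period-wise log-rIIV asks whether predictability
itself is a stable individual trait.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from owlmove import repeatability as rp

OUT = Path("results")


def main(seed: int = 7) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(OUT / "indices.csv").rename(columns={"max_disp_km": "value"})
    est = rp.estimate_repeatability(table, n_boot=1000, seed=seed)
    res = {
        "trait": "max_disp_km",
        "rp": est.rp, "rp_ci": list(est.rp_ci),
        "cvi": est.cvi, "cvi_ci": list(est.cvi_ci),
        "n_individuals": est.n_individuals, "n_obs": est.n_obs,
    }
    print(f"Rp = {est.rp:.3f} [{est.rp_ci[0]:.3f}, {est.rp_ci[1]:.3f}]  "
          f"CVi = {est.cvi:.3f} [{est.cvi_ci[0]:.3f}, {est.cvi_ci[1]:.3f}]")
    period_riiv = pd.read_csv(OUT / "riiv_period.csv")
    try:
        cons = rp.riiv_consistency(period_riiv, n_boot=1000, seed=seed)
        res["riiv_consistency_rp"] = cons.rp
        res["riiv_consistency_ci"] = list(cons.rp_ci)
        print(f"rIIV consistency across periods: Rp = {cons.rp:.3f} "
              f"[{cons.rp_ci[0]:.3f}, {cons.rp_ci[1]:.3f}]")
    except ValueError as exc:
        res["riiv_consistency_error"] = str(exc)
        print(f"rIIV consistency not estimable here: {exc}")
    with open(OUT / "repeatability.json", "w") as fh:
        json.dump(res, fh, indent=1)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
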