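"""Generate the synthetic study cohort.

Draws a cohort of tracked owls with known ground-truth behavioral types
(u_i), dispersion intercepts (v_i), nightly trajectories with planted
localization artifacts, nest-box occupancy, and survival outcomes, then
writes the raw-format CSVs plus the ground-truth JSON under
``scratch/cohort/`` (fix-level files are large and regenerable, so they
stay out of the curated ``results/`` tables).
"""

import sys
from pathlib import Path

from owlmove import simulate

OUT = Path("scratch/cohort")


def main(seed: int = 7) -> None:
    cfg = simulate.SimConfig(n_individuals=20, nights_per_individual=40, seed=seed)
    meta, truth = simulate.simulate_cohort(cfg)
    fixes, truth = simulate.simulate_tracks(cfg, truth)
    occupancy = simulate.simulate_occupancy(cfg, truth)
    paths = simulate.write_cohort(OUT, fixes, meta, truth, occupancy)
    n_art = int(fixes["artifact_std"].sum() + fixes["artifact_speed"].sum())
    print(f"cohort: {len(meta)} individuals, {len(fixes)} fixes "
          f"({n_art} planted artifacts), deaths: {int(truth.survival['event'].sum())}")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
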