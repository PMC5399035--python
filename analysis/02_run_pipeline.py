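#!/usr/bin/env python
"""Run the full sensor-to-statistics pipeline on the simulated cohort.

Preprocessing (artifact rejection, ≥15-epoch rule), posterior-channel
alpha-peak detection and IAF-anchored band definition, zero-phase FIR
filtering, LCMV beamforming, area-level PLV, and the edge-wise permutation
ANCOVA with BH-FDR plus post-hoc contrasts, RSN comparisons, score
correlations, hippocampal-volume comparison and the beamformer-weight
leakage diagnostic.  All tables land in results/pipeline/.

Requires analysis/01_simulate_cohort.py to have been run first.
"""

import json
from pathlib import Path

from alphasync.io import read_cohort
from alphasync.pipeline import RunConfig, run_pipeline
from alphasync.synthetic import default_spec

SEED = 11
OUT = Path("results/pipeline")


def main() -> None:
    subjects, _ = read_cohort("scratch/cohort")
    # the reconstruction grid is the generator's source grid + atlas
    spec = default_spec(seed=SEED, n_sensors=64, n_sources_per_area=2)
    cfg = RunConfig(seed=SEED, n_perm=2000)
    res = run_pipeline(cfg, OUT, subjects=subjects,
                       source_positions=spec.source_positions,
                       source_orientations=spec.source_orientations,
                       atlas_labels=spec.atlas_labels)
    man = res["manifest"]
    print(json.dumps({k: man[k] for k in (
        "sample_average_iaf", "band", "n_subjects",
        "n_fdr_discoveries", "n_leakage_discoveries")}, indent=1))
    disc = res["edge_stats"][res["edge_stats"]["fdr_rejected"]]
    print(f"\n{len(disc)} edges survive FDR; strongest:")
    print(disc.sort_values("p_perm").head(10).to_string(index=False))
    print("\nNote: after beamforming, anterior hyper-synchronisation is "
          "recovered reliably while posterior hypo-coupling is attenuated "
          "by source leakage (see docs/methods.md, limitations).")


if __name__ == "__main__":
    main()
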