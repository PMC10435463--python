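"""Genome-wide 10-kb bin differential occupancy with replicate consensus.

Simulates 3+3 replicate tracks with 200 genes at half occupancy in KO,
classifies every 10-kb bin per replicate pair (signal floor 1, 1.5-fold
threshold) and reports 2-of-3 consensus counts and where the lost bins lie.
"""

import occudiff as od
from occudiff.simulate import CTRL, KO, simulate_tracks

cfg = od.SimulationConfig(seed=7)
truth = od.simulate_genome(cfg)
tracks = simulate_tracks(truth)

table = od.diff_bins(tracks[CTRL], tracks[KO])
counts = table.counts()
print(f"bins: {len(table.grid)}  consensus: {counts}")

dist = od.changed_bin_distribution(table, truth.geneset, cfg.annotation)
print("down-bin genomic distribution:",
      {k: f"{100 * v:.0f}%" for k, v in dist["down"].items()})
# Consensus-down bins should be concentrated over the planted genes'
# promoters and bodies; with no planted gains, consensus-up stays ~0.
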