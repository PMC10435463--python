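"""Peak annotation and canonical-motif enrichment.

Assigns each peak to its nearest TSS, summarizes the genomic distribution
of peak midpoints, and tests enrichment of the AP-1/TRE consensus TGACTCA
(either strand) against a composition-preserving shuffle null.
"""

import occudiff as od

cfg = od.SimulationConfig(seed=42)
truth = od.simulate_genome(cfg)
peakset = od.simulate_peaks(truth)

mapping = od.assign_peaks_to_genes(peakset, truth.geneset, max_distance=100_000)
targets = {g for g in mapping.values() if g is not None}
print(f"{len(peakset)} peaks assigned to {len(targets)} target genes")

dist = od.peak_genomic_distribution(peakset, truth.geneset, cfg.annotation)
print("distribution:", {k: f"{100 * v:.0f}%" for k, v in dist.items()})

obs, exp, p = od.motif_enrichment(peakset.sequences(), od.MotifSpec("TGACTCA"),
                                  n_shuffles=1000, seed=1)
print(f"peaks with a motif hit: {obs} (null expectation {exp:.1f}), p = {p:.4g}")
# With the motif planted in 80% of peaks, the observed hit count far exceeds
# the shuffle null and p reaches the minimal attainable 1/(1+n_shuffles).
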