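"""Generate a synthetic dataset with planted truth and write it to disk.

Builds a 3-chromosome genome with 1000 genes, 3 Ctrl + 3 KO coverage
replicates in which 200 genes lose half their occupancy, FPKM tables with
planted DEGs, and 200 peak sequences with the TGACTCA motif planted in 80%.
"""

import occudiff as od

cfg = od.SimulationConfig(seed=42)
truth = od.simulate_genome(cfg)
paths = od.write_fixtures(truth, "scratch/example_dataset")

print(f"genes placed:            {len(truth.geneset)}")
print(f"planted occupancy-down:  {len(truth.down_occupancy_genes)}")
print(f"planted up/down DEGs:    {len(truth.up_deg_genes)}/{len(truth.down_deg_genes)}")
print(f"peaks with motif:        {len(truth.motif_peaks)}/{cfg.n_peaks}")
print(f"files written:           {len(paths)} under scratch/example_dataset/")
# The truth sets are what the differential pipeline should recover; the
# files are ordinary chrom.sizes / BED12 / bedGraph / TSV / FASTA inputs.
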