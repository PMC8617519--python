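"""Simulate a clonal single-cell DNA dataset with known ground truth.

Builds a small two-clone "patient" — a diploid chromosomally stable (CS)
clone and a CIN clone carrying a whole-contig gain plus two half-contig
events — and prints what was generated.
"""

from cinsig.simdata import SimConfig, simulate_dataset

config = SimConfig(seed=1)
ds = simulate_dataset(config)

print(f"reference: {len(ds.reference)} contigs x {config.contig_length:,} bp")
print(f"counts matrix: {ds.counts.shape[0]} bins x {ds.counts.shape[1]} cells")
som = ds.truth.variants[~ds.truth.variants["germline"]]
print(f"variants: {len(ds.variants)} total "
      f"({int(ds.truth.variants['germline'].sum())} germline, {len(som)} somatic)")
print("\nsomatic channel counts of the CIN clone (top 5):")
print(som.query("clone == 'CIN'")["channel"].value_counts().head())
print("\nThe top channels are C[T>C]T (the SBS17a context) and the four")
print("N[T>G]T channels (SBS17b) — the mixture the CIN clone was given.")
mean_obs = ds.truth.variants["n_observed"].mean()
print(f"\nmean observing cells per variant: {mean_obs:.2f} "
      "(sparse: each cell covers only 0.5-1% of the genome)")
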