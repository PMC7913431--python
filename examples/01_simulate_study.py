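"""Generate a synthetic exosomal-miRNA study and inspect its ground truth.

Builds the three expression datasets (tissue mRNA/miRNA counts, serum
exosomal miRNA intensities), clinical covariates and a multi-source
target-prediction table, all from one seed.
"""

from exonet import simulate_study

study = simulate_study(seed=42)

print("tissue mRNA matrix:   ", study.tissue_mrna.shape, "(features x samples)")
print("tissue miRNA matrix:  ", study.tissue_mirna.shape)
counts = study.exosomal_metadata["group"].value_counts()
print("exosomal miRNA matrix:", study.exosomal_mirna.shape,
      f"-> {int(counts['tumor'])} tumor / {int(counts['normal'])} control")
print("target table rows:    ", len(study.target_table))

truth = study.truth
print("\nplanted DE features:  ",
      {k: len(v) for k, v in truth.planted_de.items()})
print("planted key features: ",
      {k: sorted(map(str, v)) for k, v in truth.planted_key.items()})
print("planted edges:        ", len(truth.planted_edges),
      "e.g.", [(str(a), str(b)) for a, b in sorted(truth.planted_edges)[:3]])

# The exosomal cohort reproduces the severe class imbalance (88 cancer
# sera vs 11 healthy controls) that motivates balanced subsampling, and
# the planted key features are the ground truth the pipeline should
# recover as "key".
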