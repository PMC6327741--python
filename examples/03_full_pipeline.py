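"""End-to-end run: synthetic dataset -> features -> cross-validation.

Generates 60 proteins whose target-cysteine labels are determined by
tryptophan proximity (positives have a Trp within 3 positions,
negatives none within 15), assembles sequence-only adjacency-matrix
features and evaluates a seeded random forest with stratified 10-fold
cross-validation.
"""

from ramfeat import SyntheticSpec, assemble, crossval_10fold, generate_sequences

spec = SyntheticSpec(n_proteins=60, cys_range=(2, 2), seed=7)
sequences, sites = generate_sequences(spec)
print(f"dataset: {len(sites)} labelled cysteines in {len(sequences)} proteins")

table = assemble(sites, n_seq=6)
print(f"feature table: {table.width} columns ({list(table.blocks)})")

scores, report = crossval_10fold(table, classifier="rf", seed=7)
print("\npooled out-of-fold evaluation:")
for key, value in report.to_dict().items():
    if isinstance(value, float):
        print(f"  {key:<18} {value:.3f}")
print(f"  confusion          {report.confusion}  (TP, FP, TN, FN)")
print("\nAUC near 1 means the forest recovered the planted signal from")
print("the adjacency matrix alone; MCC is reported at the confidence")
print("threshold that maximises it.")
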