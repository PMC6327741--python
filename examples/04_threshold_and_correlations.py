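"""Threshold optimisation and the feature-label correlation profile.

The classifier emits confidences in [0, 1]; the Matthews correlation
coefficient depends on where that confidence is cut.  The sweep finds
the cut that maximises it.  The correlation profile then asks a
model-free question: do individual feature columns correlate with the
label more than random columns would?
"""

import numpy as np

from ramfeat import (
    PROTEIN_ALPHABET,
    SyntheticSpec,
    assemble,
    crossval_10fold,
    feature_label_correlation_profile,
    generate_sequences,
    mcc,
    optimal_mcc_threshold,
)
from ramfeat.evaluate import _confusion

spec = SyntheticSpec(n_proteins=60, cys_range=(2, 2), seed=3)
_, sites = generate_sequences(spec)
table = assemble(sites, n_seq=6)
scores, report = crossval_10fold(table, seed=3)

threshold, best = optimal_mcc_threshold(scores)
at_half = mcc(*_confusion(scores.scores, scores.labels, 0.5))
print(f"MCC at threshold 0.50 : {at_half:.3f}")
print(f"optimal threshold     : {threshold:.3f}  ->  MCC {best:.3f}")
print("(the sweep can only improve on any fixed cut)")

profile = feature_label_correlation_profile(table, seed=3)
w = PROTEIN_ALPHABET.index("W")
strongest = int(np.argmax(np.abs(profile.correlations)))
print(f"\nstrongest feature-label correlation: column {strongest} "
      f"({table.column_names[strongest]}), r = {profile.correlations[strongest]:.3f}")
print(f"tryptophan-row columns are {w * 6}..{w * 6 + 5}: the signal sits "
      "exactly where it was planted, with negative sign (closer Trp ->")
print("positive label). KS test vs random columns: "
      f"D = {profile.ks_statistic:.3f}, p = {profile.ks_pvalue:.3g}")
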