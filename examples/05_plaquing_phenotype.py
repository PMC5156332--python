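"""Efficiency of plaquing, resistance classes and the receptor model.

Simulates plaque-count assays at known true EOPs, classifies them, and
checks the Pip/YjaE requirement model against the published host-range
matrix of the studied phages.
"""

from c2kit.datasets import HOSTS, PHAGE_TYPES, RESISTANCE_MATRIX, WILD_TYPE_PHAGES
from c2kit.phenotype import phenotype_matrix_check, predict_resistance
from c2kit.simulate import estimate_eop, generate_plaque_data

print("simulated assays (reference titer 1e9 pfu/ml):")
for true_eop, label in ((1.0, "replicating host"), (1.5e-4, "partial restriction"),
                        (0.0, "fully resistant host")):
    df, _ = generate_plaque_data(true_eop, ref_titer=1e9, seed=5)
    res = estimate_eop(df)
    bound = "<" if res.is_upper_bound else ""
    print(f"  true EOP {true_eop:<8g} -> measured {bound}{res.eop:.3g} "
          f"({res.resistance_class}; {label})")

preds = {(p, h): predict_resistance(PHAGE_TYPES[p], HOSTS[h])
         for p in WILD_TYPE_PHAGES for h in HOSTS}
obs = {cell: RESISTANCE_MATRIX[cell] for cell in preds}
check = phenotype_matrix_check(preds, obs)
print(f"\nreceptor model vs published matrix: {check.n_cells} cells, "
      f"{check.n_violations} violations")

# Sensitive means EOP within 1 +/- 0.45; resistant means EOP (or its
# upper bound when no plaques appear) below 1e-8.  The requirement model
# - c2-type needs Pip, bIL67-type needs YjaE - reproduces every published
# cell: hosts lacking the required receptor are resistant, hosts carrying
# it may be sensitive (necessary, not sufficient).
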