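"""Receptor-gene mutation classification and truncation prediction.

Emulates characterising bacteriophage-insensitive mutants: a 2400 nt
receptor gene (the yjaE analogue, 799 aa product) is knocked out by each
mutation class seen in such survivors, and the classifier recovers the
lesion from the wild-type/mutant sequence pair alone.
"""

import numpy as np

from c2kit.annotate import classify_mutation, predict_truncation, translate_cds
from c2kit.simulate import _random_cds, generate_host_mutant

wt = _random_cds(np.random.default_rng(1), 2400)
print(f"wild-type receptor gene: {len(wt)} nt -> {len(translate_cds(wt))} aa")

for mtype in ("nonsense", "frameshift_del", "frameshift_ins", "element_insertion"):
    mut, _truth = generate_host_mutant(wt, mtype, seed=3)
    call = classify_mutation(wt, mut)
    line = (f"  {mtype:<17} -> {call.mclass}/{call.consequence} "
            f"at nt {call.position} ({call.detail})")
    if call.consequence in ("nonsense", "frameshift"):
        res = predict_truncation(call, cds_length=len(wt), mutated_seq=mut)
        line += f", truncated product {res.truncated_length} aa"
    print(line)

# A nonsense substitution truncates at a codon computable from its
# position alone (ceil(pos/3) - 1 residues); frameshifts run on to the
# first out-of-frame stop; indels in homopolymer runs are reported at the
# leftmost equivalent position, the convention used for receptor-gene
# slippage mutations; insertions >= 50 nt are called IS-element-like.
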