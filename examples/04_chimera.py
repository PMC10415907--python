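"""Detect a two-parent chimeric gene and locate its breakpoint.

Fuses the N-terminal 60 residues of one simulated group consensus to the
C-terminus of another, then scans the fusion against both parents: for
every split column b the scan counts residues explained by parent A on
[0,b) plus parent B on [b,L); the best split minus the best single parent
is the evidence for recombination.
"""

import numpy as np

import retrokit as rk
from retrokit.seqio import SequenceRecord
from retrokit.simulate import simulate_chimera

rng = np.random.default_rng(3)
aa = list("ACDEFGHIKLMNPQRSTVWY")
parent_a = SequenceRecord(id="IR-pIFITM3-like", residues="".join(rng.choice(aa, 130)))
parent_b = SequenceRecord(id="IR-pIFITM1-like", residues="".join(rng.choice(aa, 130)))

query, truth = simulate_chimera(parent_a, parent_b, 60, seq_id="gelada_chimera")
res = rk.breakpoint_scan(query, parent_a, parent_b)
print(f"query:        {query.id}")
print(f"is_chimeric:  {res.is_chimeric}  (score gain {res.score_gain:.0f})")
print(f"breakpoint:   column {res.breakpoint_col}  (truth {truth['breakpoint']})")
print(f"N-terminus:   {res.left_parent_id}  identity {res.left_identity:.2f}")
print(f"C-terminus:   {res.right_parent_id}  identity {res.right_identity:.2f}")

control = rk.breakpoint_scan(parent_a, parent_a, parent_b)
print(f"\ncontrol (pure parent A): gain {control.score_gain:.0f}, "
      f"chimeric={control.is_chimeric}")

print(
    "\nA genuine fusion explains ~70 more residues split across two parents "
    "than either parent alone; a pure single-parent query gains nothing."
)
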