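"""Group profiles, conservation statistics and a consensus-difference call.

Builds termini profiles (N-/C-terminal position weight matrices plus length
ranges) for six simulated groups, classifies a held-out noisy member,
reports the fully-conserved-site fraction of one group alignment, and makes
a G19R-style point-substitution call against a consensus.
"""

import numpy as np

import retrokit as rk
from retrokit.groups import GROUP_LABELS, consensus_sequence
from retrokit.seqio import SequenceRecord
from retrokit.simulate import simulate_group_alignments

rng = np.random.default_rng(12)
msas, consensus = simulate_group_alignments(rng, GROUP_LABELS)
profiles = [
    rk.build_group_profile(m, label, (0, 30), (m.n_cols - 40, m.n_cols))
    for label, m in msas.items()
]

# a held-out member of IR-pIFITMnwm at 10% divergence from its consensus
aa = list("ACDEFGHIKLMNPQRSTVWY")
seq = list(consensus["IR-pIFITMnwm"])
for i in range(len(seq)):
    if rng.random() < 0.10:
        seq[i] = rng.choice([c for c in aa if c != seq[i]])
call = rk.classify_sequence(SequenceRecord(id="query", residues="".join(seq)), profiles)
print(f"classified as: {call.group_label}  (margin {call.margin:.1f} bits)")

n_cons, n_cols, frac = rk.conserved_fraction(msas["IR-pIFITM1"])
print(f"IR-pIFITM1 alignment: {n_cons}/{n_cols} = {frac:.0%} sites fully conserved")

logo = rk.logo_matrix(msas["IR-pIFITM1"], mode="information")
print(f"mean per-column information: {logo.information.mean():.2f} bits "
      f"(max {np.log2(20):.2f})")

cons = consensus_sequence(msas["IR-pIFITM1"])
variant = SequenceRecord(
    id="variant", residues=cons.residues[:18] + "R" + cons.residues[19:]
)
print("consensus differences:", rk.consensus_diff(variant, cons))

print(
    "\nThe termini PWMs separate the groups cleanly despite an invariant "
    "middle domain; the consensus diff prints substitutions in standard "
    "<ref><pos><alt> notation, the form a single diagnostic group-breaking "
    "mutation takes."
)
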