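"""Assign each retrocopy to its parent transcript among paralogs.

The copy's window (200 bp upstream + CDS + 400 bp downstream, which still
contains the parent's UTR remnants) is globally aligned against each
candidate mRNA; identity over the CDS picks the parent, and near-perfect
UTR identity flags the insertion as recent.
"""

import retrokit as rk

cfg = rk.SimConfig(seed=11, genome_len=150_000, n_insertions=6,
                   copy_mutation_rate=0.01)
genome, loci, truth = rk.simulate_genome(cfg)
by_id = {l.locus_id: l for l in loci}
candidates = [p.candidate() for p in truth.parents.values()]

print("locus\tassigned\ttruth\tcds_id\tutr5_id\tutr3_id\trecent\tmargin")
for ins in truth.insertions:
    window = rk.extract_window(genome, by_id[ins.locus_id])
    pa = rk.assign_parent(window, candidates)
    fmt = lambda x: "-" if x is None else f"{x:.3f}"
    print(
        f"{ins.locus_id}\t{pa.best_parent_id}\t{ins.parent_id}\t"
        f"{pa.identity_cds:.3f}\t{fmt(pa.identity_utr5)}\t{fmt(pa.identity_utr3)}\t"
        f"{pa.recency_flag}\t{pa.margin:.3f}"
    )

print(
    "\nEven at 1% copy divergence the true parent wins by a clear identity "
    "margin over paralogs ~5% apart; recent=True means both UTRs align at "
    ">=95% identity, so the poly-A machinery marks have not yet decayed."
)
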