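# Methods

This note records the models, decision rules, tunable parameters and known
limits of each component. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and windows

Internally all coordinates are 0-based half-open; the on-disk loci table is
1-based inclusive (the convention of genome browsers this kind of
annotation is read from). A locus's analysis window is its CDS plus up to
200 bp of genomic context 5' of the canonical start and 400 bp 3' of the
canonical stop. Minus-strand loci are reverse-complemented part-wise and
swapped so "upstream" always means 5' of the coding sequence; windows
truncate silently at contig edges.

## Pairwise alignment

Global Needleman–Wunsch/Gotoh with affine gaps, executed by Biopython's
`PairwiseAligner` (C implementation) behind this package's parameter and
identity conventions. Defaults: DNA match +2 / mismatch −3 / gap open −5 /
extend −2 (EMBOSS-like); protein BLOSUM62 with open −10 / extend −1. A gap
of length k costs `open + (k−1)·extend`. The reported alignment is the
aligner's deterministic first optimum; scores are validated against an
exhaustive enumeration oracle on short sequences. Identity defaults to
matches over columns with residues in both rows ("aligned_columns"), the
right currency for comparing near-full-length copies; matches over the
shorter input is available for fragmentary queries.

## Synteny partition

A family locus is **canonical** iff it lies on the same contig as at least
one anchor gene (PGGHG, B4GALNT4, CTSD; the B4GALNT4 spelling variant
BAGALNT4 is accepted as an alias) and within distance D of the anchors'
span; everything else is **scattered**. D defaults to 500 kb on real
genomes — adjacency to named flanks is the only published criterion, so D
merely needs to exceed any real cluster's extent. A species with no anchor
at all (rearrangement or assembly gap) has its members classified
scattered with a warning, not an error, and a species with exactly one
canonical member is flagged (possible assembly gap) but not adjudicated.
Scattered loci from ≥2 species sharing both flanking genes (unordered
pair) are grouped: evidence the insertion predates the speciation.

## Hallmark detectors

* **Poly-A signal** — first exact `AATAAA` in the downstream window. The
  `ATTAAA` variant is accepted only behind an off-by-default flag; the
  canonical hexamer is the hallmark.
* **Poly-A tail** — first position p at/after the signal's 3' end (whole
  window if no signal) where p is an `A` and the 8-base window from p is
  ≥80% `A`; with a signal, p must fall within 50 bp of the signal end. The
  run end used to anchor the TSD search skips isolated non-A bases when
  the following 8 bases are still ≥6/8 `A`, so a single substitution
  inside the tail does not shift the anchor.
* **TSD** — a pair of substrings, one starting within 60 bp after the
  poly-A run end, one anywhere in the upstream window, length 6–25, with
  Hamming mismatches ≤ ⌈L/10⌉ (L1-literature-style tolerance; all
  thresholds configurable). Candidate pairs are ranked by **adjacency of
  the downstream copy to the tail end first**, then by matching bases,
  then fewest mismatches, then the upstream copy nearest the insertion.
  TPRT leaves the 3' TSD copy abutting the tail, and this ordering is what
  makes exact boundary recovery possible: ranking by raw length instead
  would systematically absorb chance flank matches into the mismatch
  budget (a length-L+1 pair with one mismatch always qualifies) and, in a
  60×200 bp search space, a chance exact 7-mer outcompetes a true 6-mer
  TSD about half the time. Every reported TSD is re-verifiable against its
  window (`verify_tsd`).
* **CDS integrity** — translate frame 0 from the canonical ATG; the first
  stop is premature when it falls before the expected final codon (the
  assigned parent's CDS length when known, else the copy's own last
  codon); `full_cds` requires no premature stop and a terminal stop.
* **Intron loss** — align the copy to the spliced parent transcript:
  "yes" when every parent exon–exon junction is spanned colinearly by ≥20
  aligned bases with ≤2 gap columns; "no" when a ≥50-base copy-only
  insertion coincides with a junction (a retained intron); "unknown"
  otherwise. The thresholds trade sensitivity against alignment noise at
  junction edges and are parameters.

**Verdict.** With ≥3 of the 4 insertion hallmarks: `retrogene` if the CDS
is intact, `retropseudogene` if not; otherwise `indeterminate` (mirroring
the cases a human curator marks "?").

## Parent assignment

The whole window (which contains any retained UTR remnants) is aligned to
each candidate mRNA; the parent maximizing CDS identity wins, ties going
to the lexicographically smallest id. UTR identities are reported when ≥30
bases align; both UTRs at ≥95% flag a **recent** event, since TSDs, signal
and tail decay with time. The margin to the runner-up quantifies
confidence among close paralogs.

## Chimera scan

Pairwise alignments of the query to each parent are projected onto query
coordinates as match indicators (`X` and gaps never match — this is what
lets a frameshifted C-terminus still be scored on identity). For every
split b, `M(b) = matches(A on [0,b)) + matches(B on [b,L))`, both
orientations; `score_gain = max M − best single parent`; chimeric when the
gain reaches `min_gain` (default 5 matched residues). The argmax of M is a
plateau wherever both parents agree with the query around the junction;
the reported breakpoint is the plateau midpoint. This is the optimal point
estimator: with parents agreeing at fraction q of positions the plateau is
1 plus two geometric(1−q) runs, the truth is uniform on it, and the
success probability of any estimator within ±5 columns is bounded by
E[min(W,11)/W] — about 0.83 at q=0.85. Breakpoints between highly similar
parents are intrinsically interval, not point, estimates.

## Group profiles and classification

A group profile is a pair of position weight matrices over designated
N- and C-terminal alignment blocks (additive pseudocount 0.5) plus the
ungapped member length ranges in those blocks. The block column intervals
are user-supplied: the informative termini boundaries come from inspection
of the curated alignment, not from an algorithm, because the central CD225
domain is nearly invariant and carries no group signal. Classification
aligns the query to each profile's consensus, sums log2 PWM probabilities
over both blocks, adds a length-compatibility flag per terminus (range ±2
residues), and takes the max; exact ties break to the alphabetically first
label and are flagged ambiguous.

Conservation counts a column as fully conserved only when all rows carry
the identical residue and none has a gap (the strictest reading). Logo
matrices report per-column residue probabilities with gaps excluded from
the denominator; information content is `log2(A) + Σ p log2 p` with no
small-sample correction (probability, not information, is the primary
display mode). All-gap columns are flagged with IC 0.

## Distance phylogeny

The partial-deletion filter keeps exactly the columns where the fraction
of rows with a real residue (not gap, not N/X) is ≥ the coverage threshold
(default 0.95; the boundary case is kept — whether the published rule used
≥ or > is unstated, so the choice is documented here). Distances:
p-distance; Poisson correction −ln(1−p) for proteins; JC69
−(3/4)ln(1−4p/3) for DNA; per-pair complete deletion of missing sites;
diverging corrections capped at 10 substitutions/site and flagged.
Maximum-likelihood distances under an empirical amino-acid model with
Γ-rate heterogeneity are out of scope; the Poisson correction is the
surrogate and the substitution is recorded here deliberately.

Neighbor-joining is the canonical Saitou–Nei algorithm with the
Studier–Keppler Q criterion; Q ties break to the lexicographically
smallest (by smallest member leaf label) pair, so the tree is a pure
function of the input matrix. Negative branch estimates are clamped to 0
and counted on the tree object. Bootstrap resamples filtered columns with
replacement, rebuilds NJ per replicate, and reports each original internal
bipartition's frequency as an integer percentage on the internal node
label; a fixed seed reproduces supports bit-exactly.

## The simulator and what a green test establishes

The generator emits a background contig at a requested GC with a canonical
cluster (three anchors; intron-bearing, strand-alternating family genes
between them) and then performs TPRT-style insertions: spliced transcript
(5' UTR + CDS + 3' UTR ending in its poly-A signal) + a 0–30 bp
cleavage-site remnant + a 10–50 bp tail, flanked by a duplicated 6–20 bp
target-site k-mer, on either strand. With probability 0.32 one internal
codon becomes a stop (the observed retropseudogene fraction among
published copies, 8/25); with probability 0.25 the 5' UTR is truncated
(truncation never reaches the CDS — copies without a canonical start fall
outside the windowed analysis by construction). Paralogous parents are
generated at ~5% pairwise divergence with codon-aware mutation (no
premature stops). Insertions never nest and keep ≥800 bp apart, and land
at least `cluster_margin` (default 20 kb) from the cluster, so a synteny
classification with a matching distance threshold has a well-defined
truth.

**Unambiguity rejection-sampling.** Insertion sites are resampled until
every planted hallmark is the unique first/best call in its window: the
planted `AATAAA` is the first in the downstream context, no earlier
position qualifies as a tail start, the A-run ends exactly at the TSD, the
planted repeat occurs once upstream, cannot be extended by chance flank
matches, and no upstream segment within the detector's mismatch budget
matches more bases of the tail-adjacent downstream than the planted copy.
Without this, boundary ground truth would be ill-defined whenever
background sequence happens to extend a repeat — the generator states a
world in which truth exists; it does not tune detector thresholds.
Consequently the mutation-free recovery tests establish implementation
consistency (the detectors find exactly what was planted, at exact
offsets), not statistical power against ambiguous real-genome contexts;
the power statements are the mutated-cohort recall and the false-positive
analyses.

Sequence evolution along a tree uses Poisson point substitutions per
branch (rate × length × sites), each replacing a residue with a uniform
different one — exactly JC69 for DNA (equal-rates for protein), no indels,
so leaves return aligned. Group alignments share one conserved middle
domain with group-specific random termini of group-specific lengths;
within-group divergence 2%.

## Known limits

* A TSD detector admitting 6 bp repeats cannot satisfy a ≤2% false-call
  rate over a 60 bp × 200 bp search space: the expected number of chance
  exact hexamer pairs alone is ≈3 per window, and the ⌈L/10⌉ mismatch
  budget raises the per-pair hit probability ~20-fold. A ≥10 bp minimum
  would meet the bound but forfeit every shorter true TSD. On real data,
  short TSD calls should be treated as corroborating, never primary,
  evidence.
* Chimera breakpoints between parents ≥85% identical are interval
  estimates (see above); report and interpret the plateau, not the point.
* The simulator omits: nested insertions, the L1 endonuclease site
  preference (insertion is uniform over background), 5' truncation into
  the CDS, indel evolution, and rate heterogeneity among sites. Green
  tests say nothing about robustness to these.
* Intron-loss calls depend on a trustworthy parent exon annotation; the
  "unknown" value is the honest output when junction coverage is thin.
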