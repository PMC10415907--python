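"""Synthetic-data generator with machine-readable ground truth.

Emulates the generative processes the analysis pipeline is built to detect:
a host contig carrying a canonical gene cluster (anchor genes plus
intron-bearing family genes), LINE-1-style retrotransposition of spliced
parent transcripts (target-site duplication, poly-A signal and tail,
optional 5' truncation and pseudogenizing nonsense mutations), two-parent
chimeric recombinants, and sequence evolution along a known tree.

Every stochastic choice flows from a caller-supplied seed; there is no
implicit randomness. Each emitted feature is recorded in a truth object
that tests verify against the sequences by direct string inspection.

Insertion sites are rejection-sampled so that every planted hallmark is
unambiguous in its window: the poly-A signal is the first AATAAA of the
downstream context, the tail is the first qualifying A-run after the
signal, and the TSD is the unique best-supported adjacent repeat. Without
this, boundary truth would be ill-defined whenever background sequence
happens to extend a repeat by chance — the generator states a world in
which ground truth exists, it does not tune detector thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .retroscan import (
    POLYA_SIGNAL,
    ParentCandidate,
    RetroWindow,
    Tsd,
    extract_window,
    polya_run_end,
)
from .seqio import GeneLocus, Msa, SequenceRecord

_DNA = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _DNA
    for b in _DNA
    for c in _DNA
    if a + b + c not in ("TAA", "TAG", "TGA")
]
STOPS = ("TAA", "TAG", "TGA")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """World parameters for the retrotransposition simulator.

    Defaults: a 100 kb contig at GC 0.5 with 10 insertions; TSD lengths
    uniform on [6, 20] and tail lengths on [10, 50] (bracketing typical
    L1-mediated values); signal-to-tail gap uniform on [0, 30] (transcript
    cleavage heterogeneity); nonsense probability 0.32 (the observed
    retropseudogene fraction, 8 of 25 copies); 5'-UTR truncation
    probability 0.25; no copy mutations unless asked for.
    """

    seed: int
    genome_len: int = 100_000
    gc: float = 0.5
    n_insertions: int = 10
    tsd_len_range: Tuple[int, int] = (6, 20)
    tail_len_range: Tuple[int, int] = (10, 50)
    copy_mutation_rate: float = 0.0
    nonsense_probability: float = 0.32
    truncation_probability: float = 0.25
    signal_tail_gap_range: Tuple[int, int] = (0, 30)
    n_family_genes: int = 3
    cds_n_aa: int = 130
    utr5_len: int = 60
    utr3_len: int = 80
    intron_len: int = 200
    # retro-insertions land at least this far from the canonical cluster, so
    # a synteny classification with max_dist <= cluster_margin (and >= the
    # cluster span) separates the two classes perfectly on simulated data
    cluster_margin: int = 20_000

    def __post_init__(self) -> None:
        for lo, hi in (self.tsd_len_range, self.tail_len_range, self.signal_tail_gap_range):
            if lo > hi:
                raise ValueError("empty range in config")
        for rate in (self.copy_mutation_rate, self.nonsense_probability,
                     self.truncation_probability, self.gc):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")


class PlacementError(ValueError):
    """No room to place a feature in the genome."""


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_DNA), size=n, p=p))


@dataclass
class ParentGene:
    """An intron-bearing family gene and its spliced transcript."""

    name: str
    utr5: str
    cds_exon1: str
    intron: str
    cds_exon2: str
    utr3: str  # includes the terminal AATAAA

    @property
    def cds(self) -> str:
        return self.cds_exon1 + self.cds_exon2

    @property
    def mrna(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def genomic(self) -> str:
        return self.utr5 + self.cds_exon1 + self.intron + self.cds_exon2 + self.utr3

    @property
    def exon_lengths(self) -> List[int]:
        # exon/exon junction position within the spliced transcript
        return [
            len(self.utr5) + len(self.cds_exon1),
            len(self.cds_exon2) + len(self.utr3),
        ]

    @property
    def cds_span(self) -> Tuple[int, int]:
        return len(self.utr5), len(self.utr5) + len(self.cds)

    def candidate(self) -> ParentCandidate:
        lo, hi = self.cds_span
        return ParentCandidate(
            mrna=SequenceRecord(id=self.name, residues=self.mrna),
            cds_start=lo,
            cds_end=hi,
            exon_lengths=self.exon_lengths,
        )


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_aa - 1))
    return "ATG" + body + str(rng.choice(list(STOPS)))


def _utr3_with_signal(rng: np.random.Generator, core_len: int, gc: float) -> str:
    """3' UTR whose first AATAAA is the planted terminal signal."""
    for _ in range(200):
        core = random_dna(rng, core_len, gc)
        utr3 = core + POLYA_SIGNAL
        if utr3.find(POLYA_SIGNAL) == core_len:
            return utr3
    raise PlacementError("could not sample an AATAAA-free 3' UTR core")


def make_parent_gene(rng: np.random.Generator, name: str, config: SimConfig) -> ParentGene:
    cds = _random_cds(rng, config.cds_n_aa + 1)
    split = 3 * int(rng.integers(20, config.cds_n_aa - 20))
    intron = "GT" + random_dna(rng, config.intron_len - 4, config.gc) + "AG"
    return ParentGene(
        name=name,
        utr5=random_dna(rng, config.utr5_len, config.gc),
        cds_exon1=cds[:split],
        intron=intron,
        cds_exon2=cds[split:],
        utr3=_utr3_with_signal(rng, config.utr3_len, config.gc),
    )


def make_parent_family(
    rng: np.random.Generator,
    config: SimConfig,
    n: int = 3,
    divergence: float = 0.05,
) -> List[ParentGene]:
    """A family of paralogous parents at ~``divergence`` pairwise distance.

    Each paralog is mutated from a common base gene at half the requested
    pairwise divergence; CDS mutations are codon-resampled so no paralog
    gains a premature stop, and the 3' UTR keeps its planted first-AATAAA
    property.
    """
    base = make_parent_gene(rng, "parent", config)

    def mutate_seq(s: str, rate: float) -> str:
        out = list(s)
        for i in range(len(out)):
            if rng.random() < rate:
                out[i] = rng.choice([b for b in _DNA if b != out[i]])
        return "".join(out)

    def mutate_cds(cds: str, rate: float) -> str:
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for ci in range(1, len(codons) - 1):
            codon = list(codons[ci])
            for k in range(3):
                if rng.random() < rate:
                    codon[k] = rng.choice([b for b in _DNA if b != codon[k]])
            cand = "".join(codon)
            if cand in STOPS:
                cand = str(rng.choice(_SENSE_CODONS))
            codons[ci] = cand
        return "".join(codons)

    family = []
    half = divergence / 2
    for i in range(n):
        cds = mutate_cds(base.cds, half)
        split = len(base.cds_exon1)
        for _ in range(200):
            utr3 = mutate_seq(base.utr3[: -len(POLYA_SIGNAL)], half) + POLYA_SIGNAL
            if utr3.find(POLYA_SIGNAL) == len(utr3) - len(POLYA_SIGNAL):
                break
        family.append(
            ParentGene(
                name=f"IFITM_L{i + 1}",
                utr5=mutate_seq(base.utr5, half),
                cds_exon1=cds[:split],
                intron=mutate_seq(base.intron[2:-2], half).join(("GT", "AG")),
                cds_exon2=cds[split:],
                utr3=utr3,
            )
        )
    return family


@dataclass
class InsertionTruth:
    locus_id: str
    parent_id: str
    insertion_pos: int  # genome coordinate of the locus (CDS) start
    strand: str
    tsd_sequence: str  # coding orientation
    tsd_len: int
    signal_pos: int  # offsets within the downstream window
    tail_start: int
    tail_len: int
    premature_stop: Optional[int]  # 1-based codon index, or None
    truncated_5prime: bool
    utr5_retained: int
    planted_mutations: List[Tuple[int, str, str]] = field(default_factory=list)


@dataclass
class SimTruth:
    parents: Dict[str, ParentGene] = field(default_factory=dict)
    cluster_locus_ids: List[str] = field(default_factory=list)
    cluster_span: Optional[Tuple[int, int]] = None
    insertions: List[InsertionTruth] = field(default_factory=list)
    chimeras: List[dict] = field(default_factory=list)
    tree_newick: Optional[str] = None


def _mismatch_budget(length: int, per10: int = 1) -> int:
    return math.ceil(length / 10) * per10


def _window_is_unambiguous(
    window: RetroWindow,
    truth: InsertionTruth,
    max_len: int = 25,
) -> bool:
    """True when every planted hallmark is the first/best call in its window.

    Checks, by direct string inspection: the planted AATAAA is the first in
    the downstream context; no earlier position qualifies as a tail start;
    the poly-A run ends exactly at the TSD; and no upstream segment rivals
    the planted TSD (same adjacency, at least as many matching bases within
    the detector mismatch budget) other than the planted copy itself.
    """
    down, up = window.downstream, window.upstream
    if down.find(POLYA_SIGNAL) != truth.signal_pos:
        return False
    # no qualifying tail start before the planted one
    for p in range(truth.signal_pos + len(POLYA_SIGNAL), truth.tail_start):
        if down[p] == "A" and down[p : p + 8].count("A") >= 7:
            return False
    run_end = polya_run_end(down, truth.tail_start)
    if run_end != truth.tail_start + truth.tail_len:
        return False
    L = truth.tsd_len
    tsd_down = down[run_end : run_end + L]
    if tsd_down != truth.tsd_sequence:
        return False
    if up.count(truth.tsd_sequence) != 1:
        return False
    u = up.find(truth.tsd_sequence)
    # no chance extension of the planted pair in either direction
    if u > 0 and up[u - 1] == "A":
        return False
    if u + L < len(up) and run_end + L < len(down) and up[u + L] == down[run_end + L]:
        return False
    # no rival adjacent pair matching more bases within the mismatch budget
    up_arr = np.frombuffer(up.encode(), dtype=np.uint8)
    for L2 in range(L + 1, max_len + 1):
        if run_end + L2 > len(down) or L2 > len(up):
            break
        probe = np.frombuffer(down[run_end : run_end + L2].encode(), dtype=np.uint8)
        wins = np.lib.stride_tricks.sliding_window_view(up_arr, L2)
        mism = (wins != probe[None, :]).sum(axis=1)
        ok = mism <= _mismatch_budget(L2)
        if np.any(ok & ((L2 - mism) > L)):
            return False
    return True


def simulate_retrotransposition(
    parent: ParentGene,
    genome: SequenceRecord,
    config: SimConfig,
    rng: np.random.Generator,
    forbidden: Optional[List[Tuple[int, int]]] = None,
    locus_id: str = "retro1",
    margin: int = 800,
    max_tries: int = 400,
) -> Tuple[SequenceRecord, GeneLocus, InsertionTruth]:
    """Insert one retrotransposed copy of ``parent`` into ``genome``.

    The inserted unit is the spliced transcript (5' UTR + CDS + 3' UTR,
    the 3' UTR ending in its poly-A signal) followed by a cleavage-site
    remnant and a poly-A tail; the target-site k-mer is duplicated flanking
    the unit. With the configured probabilities the 5' UTR is truncated
    and/or one internal codon becomes a stop. Copy mutations are applied
    over the whole inserted footprint (both TSD copies included) after the
    unambiguity checks.
    """
    forbidden = list(forbidden or [])
    g = genome.residues
    up_w, down_w = 200, 400

    for _ in range(max_tries):
        k = int(rng.integers(config.tsd_len_range[0], config.tsd_len_range[1] + 1))
        tail_len = int(rng.integers(config.tail_len_range[0], config.tail_len_range[1] + 1))
        gap_len = int(
            rng.integers(config.signal_tail_gap_range[0], config.signal_tail_gap_range[1] + 1)
        )
        pos = int(rng.integers(margin, len(g) - margin))
        if any(s - margin <= pos <= e + margin for s, e in forbidden):
            continue
        strand = "+" if rng.random() < 0.5 else "-"

        utr5 = parent.utr5
        truncated = rng.random() < config.truncation_probability
        if truncated and len(utr5) > 2:
            cut = int(rng.integers(1, len(utr5) - 1))
            utr5 = utr5[cut:]

        cds = parent.cds
        premature = None
        if rng.random() < config.nonsense_probability:
            n_codons = len(cds) // 3
            ci = int(rng.integers(2, n_codons))  # 1-based codon index, internal
            cds = cds[: 3 * (ci - 1)] + str(rng.choice(list(STOPS))) + cds[3 * ci :]
            premature = ci

        gap = random_dna(rng, gap_len, config.gc)
        unit = utr5 + cds + parent.utr3 + gap
        tail = "A" * tail_len
        kmer = g[pos : pos + k]
        if kmer[0] == "A":  # tail-TSD boundary would be ambiguous
            continue

        insert = unit + tail
        if strand == "-":
            rc = SequenceRecord(id="x", residues=insert).reverse_complement().residues
            new_g = g[: pos + k] + rc + g[pos:]
            cds_end_g = pos + k + tail_len + len(parent.utr3) + len(gap) + len(cds)
            locus = GeneLocus(
                locus_id=locus_id,
                species="sim",
                contig=genome.id,
                start=cds_end_g - len(cds),
                end=cds_end_g,
                strand="-",
                gene_name=f"IFITM_{locus_id}",
                exon_count=1,
            )
            tsd_seq = (
                SequenceRecord(id="x", residues=kmer).reverse_complement().residues
            )
        else:
            new_g = g[: pos + k] + insert + g[pos:]
            cds_start_g = pos + k + len(utr5)
            locus = GeneLocus(
                locus_id=locus_id,
                species="sim",
                contig=genome.id,
                start=cds_start_g,
                end=cds_start_g + len(cds),
                strand="+",
                gene_name=f"IFITM_{locus_id}",
                exon_count=1,
            )
            tsd_seq = kmer

        # downstream window offsets: UTR3 core, then AATAAA, then gap, then tail
        truth = InsertionTruth(
            locus_id=locus_id,
            parent_id=parent.name,
            insertion_pos=locus.start,
            strand=strand,
            tsd_sequence=tsd_seq,
            tsd_len=k,
            signal_pos=len(parent.utr3) - len(POLYA_SIGNAL),
            tail_start=len(parent.utr3) + gap_len,
            tail_len=tail_len,
            premature_stop=premature,
            truncated_5prime=truncated,
            utr5_retained=len(utr5),
        )

        new_genome = SequenceRecord(id=genome.id, residues=new_g, description=genome.description)
        window = extract_window(new_genome, locus, up=up_w, down=down_w)
        if not _window_is_unambiguous(window, truth):
            continue

        if config.copy_mutation_rate > 0:
            footprint = (pos, pos + 2 * k + len(insert))
            seq = list(new_g)
            for i in range(*footprint):
                if rng.random() < config.copy_mutation_rate:
                    old = seq[i]
                    seq[i] = rng.choice([b for b in _DNA if b != old])
                    truth.planted_mutations.append((i, old, seq[i]))
            new_genome = SequenceRecord(
                id=genome.id, residues="".join(seq), description=genome.description
            )
        return new_genome, locus, truth

    raise PlacementError(
        f"no unambiguous insertion site found for {locus_id} after {max_tries} tries"
    )


ANCHORS = ("PGGHG", "B4GALNT4", "CTSD")


def simulate_genome(config: SimConfig) -> Tuple[SequenceRecord, List[GeneLocus], SimTruth]:
    """A host contig with a canonical cluster plus scattered retro-insertions.

    The cluster carries the three anchor genes with the family genes
    (intron-bearing, strand-alternating) between the first two anchors;
    ``config.n_insertions`` retrocopies of the family genes are then placed
    uniformly over the background, never inside the cluster or another
    insertion's neighborhood. Fully deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    parents = make_parent_family(rng, config, n=config.n_family_genes)
    for p in parents:
        truth.parents[p.name] = p

    anchor_len, spacer = 1000, 300
    cluster_parts: List[Tuple[Optional[str], str, str, Optional[ParentGene]]] = []
    cluster_parts.append((ANCHORS[0], random_dna(rng, anchor_len, config.gc), "+", None))
    for i, p in enumerate(parents):
        strand = "+" if i % 2 == 0 else "-"
        seq = p.genomic
        if strand == "-":
            seq = SequenceRecord(id="x", residues=seq).reverse_complement().residues
        cluster_parts.append((p.name, seq, strand, p))
    cluster_parts.append((ANCHORS[1], random_dna(rng, anchor_len, config.gc), "+", None))
    cluster_parts.append((ANCHORS[2], random_dna(rng, anchor_len, config.gc), "+", None))

    cluster_len = sum(len(s) for _, s, _, _ in cluster_parts) + spacer * (
        len(cluster_parts) + 1
    )
    if config.genome_len < cluster_len + 20_000:
        raise PlacementError(
            f"genome of {config.genome_len} bp too short for the cluster "
            f"({cluster_len} bp) plus background"
        )

    cluster_start = 5_000
    pieces = [random_dna(rng, cluster_start, config.gc)]
    loci: List[GeneLocus] = []
    cursor = cluster_start
    names = [name for name, _, _, _ in cluster_parts]
    for idx, (name, seq, strand, parent) in enumerate(cluster_parts):
        pieces.append(random_dna(rng, spacer, config.gc))
        cursor += spacer
        if parent is not None:
            if strand == "+":
                start = cursor + len(parent.utr5)
                end = start + len(parent.cds) + len(parent.intron)
            else:
                start = cursor + len(parent.utr3)
                end = start + len(parent.cds) + len(parent.intron)
        else:
            start, end = cursor, cursor + len(seq)
        loci.append(
            GeneLocus(
                locus_id=f"cluster_{name}",
                species="sim",
                contig="chr_sim",
                start=start,
                end=end,
                strand=strand,
                gene_name=name if parent is None else name,
                exon_count=2 if parent is not None else 1,
                upstream_gene=names[idx - 1] if idx > 0 else None,
                downstream_gene=names[idx + 1] if idx + 1 < len(names) else None,
            )
        )
        if parent is not None:
            truth.cluster_locus_ids.append(f"cluster_{name}")
        pieces.append(seq)
        cursor += len(seq)
    pieces.append(random_dna(rng, spacer, config.gc))
    cursor += spacer
    cluster_end = cursor
    truth.cluster_span = (cluster_start, cluster_end)
    pieces.append(random_dna(rng, config.genome_len - cursor, config.gc))
    genome = SequenceRecord(
        id="chr_sim", residues="".join(pieces), description="chr_sim simulated contig"
    )

    forbidden: List[Tuple[int, int]] = [(0, cluster_end + config.cluster_margin)]
    for i in range(config.n_insertions):
        parent = parents[i % len(parents)]
        before = len(genome.residues)
        genome, locus, ins = simulate_retrotransposition(
            parent, genome, config, rng, forbidden=forbidden, locus_id=f"retro{i + 1}"
        )
        # shift bookkeeping: everything at or beyond the insertion moved right
        shift = len(genome.residues) - before
        ins_start = locus.start - 700
        forbidden = [
            (s + shift, e + shift) if s >= ins_start else (s, e) for s, e in forbidden
        ]
        for lo in loci:
            if lo.start >= ins_start:
                lo.start += shift
                lo.end += shift
        for prev in truth.insertions:
            if prev.insertion_pos >= ins_start:
                prev.insertion_pos += shift
        forbidden.append((locus.start - 700, locus.end + 700))
        loci.append(locus)
        truth.insertions.append(ins)
    return genome, loci, truth


def simulate_chimera(
    parent_a: SequenceRecord,
    parent_b: SequenceRecord,
    breakpoint,
    rng: Optional[np.random.Generator] = None,
    mutation_rate: float = 0.0,
    seq_id: str = "chimera",
) -> Tuple[SequenceRecord, dict]:
    """A two-parent recombinant: ``parent_a[:b] + parent_b[b:]``."""
    max_b = min(len(parent_a.residues), len(parent_b.residues))
    if breakpoint == "random":
        if rng is None:
            raise ValueError("random breakpoint requires an rng")
        b = int(rng.integers(1, max_b))
    else:
        b = int(breakpoint)
    if not (0 <= b <= max_b):
        raise ValueError(f"breakpoint {b} out of range [0, {max_b}]")
    residues = parent_a.residues[:b] + parent_b.residues[b:]
    if mutation_rate > 0:
        if rng is None:
            raise ValueError("mutations require an rng")
        alphabet = _AA20 if set(residues) - set(_DNA) else _DNA
        out = list(residues)
        for i in range(len(out)):
            if rng.random() < mutation_rate:
                out[i] = rng.choice([c for c in alphabet if c != out[i]])
        residues = "".join(out)
    truth = {
        "left_parent": parent_a.id,
        "right_parent": parent_b.id,
        "breakpoint": b,
    }
    return SequenceRecord(id=seq_id, residues=residues), truth


def random_tree(
    rng: np.random.Generator,
    taxa: Sequence[str],
    branch_length_range: Tuple[float, float] = (0.02, 0.12),
) -> dendropy.Tree:
    """A random binary topology with uniform branch lengths."""
    ns = dendropy.TaxonNamespace(list(taxa))
    nodes = []
    for t in taxa:
        node = dendropy.Node(taxon=ns.get_taxon(t))
        node.edge.length = float(rng.uniform(*branch_length_range))
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(*branch_length_range))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    for n in nodes:
        tree.seed_node.add_child(n)
    return tree


def evolve_sequences(
    tree: dendropy.Tree,
    root_seq: SequenceRecord,
    subst_rate: float = 1.0,
    seed: int = 0,
) -> Tuple[Msa, dendropy.Tree]:
    """Evolve a root sequence down a tree by Poisson point substitutions.

    Per branch, Poisson(rate * branch_length * n_sites) substitutions are
    placed at uniform positions, each replacing the residue with a uniform
    different one (Jukes-Cantor for DNA, equal-rates for protein). No
    indels, so the leaves come back aligned.
    """
    rng = np.random.default_rng(seed)
    alphabet = _DNA if set(root_seq.residues) <= set("ACGTN") else _AA20
    n = len(root_seq.residues)
    seqs: Dict[int, str] = {id(tree.seed_node): root_seq.residues}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        blen = node.edge.length or 0.0
        n_sub = int(rng.poisson(subst_rate * blen * n))
        out = list(parent_seq)
        for _ in range(n_sub):
            i = int(rng.integers(n))
            out[i] = rng.choice([c for c in alphabet if c != out[i]])
        seqs[id(node)] = "".join(out)
    records = [
        SequenceRecord(id=leaf.taxon.label, residues=seqs[id(leaf)])
        for leaf in tree.leaf_node_iter()
    ]
    records.sort(key=lambda r: r.id)
    msa = Msa(records=records, alphabet="dna" if alphabet is _DNA else "protein")
    return msa, tree


def simulate_group_alignments(
    rng: np.random.Generator,
    group_labels: Sequence[str],
    n_members: int = 8,
    within_divergence: float = 0.02,
    middle_len: int = 60,
    n_term_range: Tuple[int, int] = (18, 30),
    c_term_range: Tuple[int, int] = (15, 40),
) -> Tuple[Dict[str, Msa], Dict[str, str]]:
    """Per-group protein alignments with group-specific termini.

    All groups share one highly conserved middle domain (the CD225
    analogue); each group gets its own random N- and C-terminal sequence
    and length. Members are the group consensus with ``within_divergence``
    random substitutions; no indels, so each group alignment is the padded
    block [N | middle | C] with '-' fill to the longest termini.
    """
    aa = list(_AA20)
    middle = "".join(rng.choice(aa, size=middle_len))
    n_lens = {g: int(rng.integers(*n_term_range)) for g in group_labels}
    c_lens = {g: int(rng.integers(*c_term_range)) for g in group_labels}
    max_n, max_c = max(n_lens.values()), max(c_lens.values())
    consensus: Dict[str, str] = {}
    msas: Dict[str, Msa] = {}
    for g in group_labels:
        n_term = "M" + "".join(rng.choice(aa, size=n_lens[g] - 1))
        c_term = "".join(rng.choice(aa, size=c_lens[g]))
        consensus[g] = n_term + middle + c_term
        members = []
        for m in range(n_members):
            seq = list(consensus[g])
            for i in range(len(seq)):
                if rng.random() < within_divergence:
                    seq[i] = rng.choice([c for c in aa if c != seq[i]])
            padded = (
                "-" * (max_n - n_lens[g])
                + "".join(seq[: n_lens[g]])
                + "".join(seq[n_lens[g] : n_lens[g] + middle_len])
                + "".join(seq[n_lens[g] + middle_len :])
                + "-" * (max_c - c_lens[g])
            )
            members.append(SequenceRecord(id=f"{g}_m{m + 1}", residues=padded))
        msas[g] = Msa(records=members, alphabet="protein")
    return msas, consensus
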