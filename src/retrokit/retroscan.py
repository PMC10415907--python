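"""Retrogene hallmark scanner.

A processed (retrotransposed) gene copy carries a characteristic signature
left by LINE-1 target-site primed reverse transcription: the copy lacks the
parent's introns, retains the poly-A signal hexamer AATAAA and the genomic
remnant of the poly-A tail, and is flanked by a short direct repeat (the
target-site duplication, TSD) whose two copies sit upstream of the canonical
start codon and immediately after the tail. Loss of coding capacity
(premature stop, missing canonical stop) downgrades a retrogene to a
retropseudogene.

The scanner consumes a :class:`RetroWindow` — the copy's CDS plus 200 bp of
genomic context upstream of the canonical start and 400 bp downstream of the
canonical stop, strand-normalized to coding orientation — and emits one
:class:`RetroFeatureReport` per locus, one row of the hallmark table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .align import AlignParams, PairwiseAlignment, global_align, percent_identity
from .seqio import GAP, CoordinateError, GeneLocus, SequenceRecord

POLYA_SIGNAL = "AATAAA"
POLYA_SIGNAL_VARIANT = "ATTAAA"

STOP_CODONS = {"TAA", "TAG", "TGA"}

# codon -> amino acid, '*' for stop (standard code)
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AA[i * 16 + j * 4 + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def translate(cds: str) -> str:
    """Translate frame 0; incomplete trailing codon ignored; N -> X."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa.append(CODON_TABLE.get(cds[i : i + 3], "X"))
    return "".join(aa)


class NoCanonicalStartError(ValueError):
    """The body does not begin with ATG."""


@dataclass
class RetroWindow:
    """A locus in coding orientation with its genomic context.

    ``upstream``: up to ``up`` bp immediately 5' of the canonical start;
    ``body``: canonical start..stop inclusive; ``downstream``: up to
    ``down`` bp immediately 3' of the canonical stop.
    """

    locus_id: str
    upstream: str
    body: str
    downstream: str


@dataclass
class Tsd:
    """A target-site duplication: the same short sequence found upstream of
    the start codon and just after the poly-A tail."""

    sequence: str
    upstream_pos: int  # 0-based offset of the copy within the upstream window
    downstream_pos: int  # 0-based offset of the copy within the downstream window
    length: int
    mismatches: int


@dataclass
class ParentAssignment:
    best_parent_id: str
    identity_cds: float
    identity_utr5: Optional[float]
    identity_utr3: Optional[float]
    margin: float
    recency_flag: bool
    all_identities: dict = field(default_factory=dict)


@dataclass
class RetroFeatureReport:
    """One hallmark-table row: the five feature calls plus the verdict."""

    locus_id: str
    lacks_intron: str  # yes | no | unknown
    polya_signal_pos: Optional[int]
    polya_tail_start: Optional[int]
    tsd: Optional[Tsd]
    premature_stop_codon_index: Optional[int]
    full_cds: bool
    verdict: str  # retrogene | retropseudogene | indeterminate

    @property
    def n_hallmarks(self) -> int:
        return sum(
            [
                self.lacks_intron == "yes",
                self.polya_signal_pos is not None,
                self.polya_tail_start is not None,
                self.tsd is not None,
            ]
        )


def extract_window(
    genome: SequenceRecord, locus: GeneLocus, up: int = 200, down: int = 400
) -> RetroWindow:
    """Cut the locus body plus flanking context, strand-normalized.

    For minus-strand loci all three parts are reverse-complemented and
    swapped so that ``upstream`` is always 5' of the coding sequence.
    Windows are truncated silently at contig edges.
    """
    if up < 0 or down < 0:
        raise ValueError("window sizes must be non-negative")
    n = len(genome.residues)
    if locus.start < 0 or locus.end > n:
        raise CoordinateError(
            f"locus {locus.locus_id} [{locus.start},{locus.end}) outside "
            f"contig {genome.id} of length {n}"
        )
    seq = genome.residues
    body = seq[locus.start : locus.end]
    left = seq[max(0, locus.start - (up if locus.strand == "+" else down)) : locus.start]
    right = seq[locus.end : locus.end + (down if locus.strand == "+" else up)]
    if locus.strand == "+":
        return RetroWindow(locus.locus_id, upstream=left, body=body, downstream=right)
    rc = lambda s: str(SequenceRecord(id="x", residues=s).reverse_complement().residues) if s else s
    return RetroWindow(
        locus.locus_id, upstream=rc(right), body=rc(body), downstream=rc(left)
    )


def find_polya_signal(
    window: RetroWindow, allow_attaaa: bool = False
) -> Optional[int]:
    """Offset of the first AATAAA hexamer in the downstream context.

    The ATTAAA variant is only considered when ``allow_attaaa`` is set (off
    by default; the canonical hexamer is the hallmark).
    """
    pos = window.downstream.find(POLYA_SIGNAL)
    if allow_attaaa:
        alt = window.downstream.find(POLYA_SIGNAL_VARIANT)
        if alt != -1 and (pos == -1 or alt < pos):
            pos = alt
    return None if pos == -1 else pos


def find_polya_tail(
    window: RetroWindow,
    signal_pos: Optional[int],
    min_run: int = 8,
    purity: float = 0.8,
    max_gap_to_signal: int = 50,
) -> Optional[int]:
    """Offset of the poly-A tail start in the downstream context.

    The tail start is the first position ``p`` at or after the signal's 3'
    end (anywhere when no signal was found) such that position ``p`` is an A
    and the window ``[p, p+min_run)`` is at least ``purity`` A. With a
    signal, ``p`` must lie within ``max_gap_to_signal`` bases of the
    signal end.
    """
    down = window.downstream
    if signal_pos is not None:
        lo = signal_pos + len(POLYA_SIGNAL)
        hi = min(len(down) - min_run, lo + max_gap_to_signal)
    else:
        lo, hi = 0, len(down) - min_run
    need = math.ceil(purity * min_run)
    for p in range(lo, hi + 1):
        if down[p] != "A":
            continue
        if down[p : p + min_run].count("A") >= need:
            return p
    return None


def polya_run_end(downstream: str, tail_start: int) -> int:
    """End (exclusive) of the poly-A run starting at tail_start.

    Isolated non-A bases are skipped when the following 8 bases are still
    >= 6/8 A, so a point substitution inside the tail does not truncate the
    run (and shift the TSD search anchor) prematurely.
    """
    n = len(downstream)
    p = tail_start
    while p < n:
        if downstream[p] == "A":
            p += 1
        elif downstream[p + 1 : p + 9].count("A") >= 6:
            p += 1
        else:
            break
    return p


def _mismatch_budget(length: int, max_mismatch_per_10bp: int) -> int:
    return math.ceil(length / 10) * max_mismatch_per_10bp


def find_tsd(
    window: RetroWindow,
    tail_start: int,
    min_len: int = 6,
    max_len: int = 25,
    max_mismatch_per_10bp: int = 1,
    search_after_tail: int = 60,
) -> Optional[Tsd]:
    """Find the target-site duplication flanking the insertion.

    One copy must start within ``search_after_tail`` bases after the poly-A
    run end; the matching copy may lie anywhere in the upstream window. A
    pair of length L qualifies when its Hamming mismatches are at most
    ``ceil(L/10) * max_mismatch_per_10bp``.

    TPRT leaves the 3' TSD copy abutting the tail, so candidate pairs are
    ranked by proximity of the downstream copy to the tail end first, then
    by number of matching bases, then fewest mismatches, then by the
    upstream copy closest to the insertion. Ranking by raw length instead
    would systematically overshoot the boundary by absorbing chance flank
    matches into the mismatch budget.
    """
    up, down = window.upstream, window.downstream
    run_end = polya_run_end(down, tail_start)
    region = down[run_end : run_end + search_after_tail + max_len]
    if len(up) < min_len or len(region) < min_len:
        return None
    up_arr = np.frombuffer(up.encode(), dtype=np.uint8)
    reg_arr = np.frombuffer(region.encode(), dtype=np.uint8)

    best: Optional[Tuple[int, int, int, int, int]] = None  # key + (s, u, L)
    max_s = min(search_after_tail, len(region) - min_len)
    for length in range(min_len, max_len + 1):
        if len(up) < length or len(region) < length:
            break
        budget = _mismatch_budget(length, max_mismatch_per_10bp)
        u_win = np.lib.stride_tricks.sliding_window_view(up_arr, length)
        r_win = np.lib.stride_tricks.sliding_window_view(reg_arr, length)
        r_win = r_win[: max_s + 1]
        # mismatch counts for every (downstream start, upstream start) pair
        mism = (r_win[:, None, :] != u_win[None, :, :]).sum(axis=2)
        ss, uu = np.nonzero(mism <= budget)
        for s, u in zip(ss.tolist(), uu.tolist()):
            m = int(mism[s, u])
            key = (s, -(length - m), m, -u)
            if best is None or key < best[:4]:
                best = key + (length,)
    if best is None:
        return None
    s, _negmatch, m, neg_u, length = best
    u = -neg_u
    return Tsd(
        sequence=down[run_end + s : run_end + s + length],
        upstream_pos=u,
        downstream_pos=run_end + s,
        length=length,
        mismatches=m,
    )


def verify_tsd(window: RetroWindow, tsd: Tsd, max_mismatch_per_10bp: int = 1) -> bool:
    """Re-check a reported TSD against its window (mismatch budget audit)."""
    a = window.upstream[tsd.upstream_pos : tsd.upstream_pos + tsd.length]
    b = window.downstream[tsd.downstream_pos : tsd.downstream_pos + tsd.length]
    if len(a) != tsd.length or len(b) != tsd.length or b != tsd.sequence:
        return False
    mism = sum(1 for x, y in zip(a, b) if x != y)
    return mism == tsd.mismatches and mism <= _mismatch_budget(
        tsd.length, max_mismatch_per_10bp
    )


def detect_cds_integrity(
    body: str, expected_aa_len: Optional[int] = None
) -> Tuple[Optional[int], bool]:
    """Locate a premature stop and judge coding completeness.

    Returns ``(premature_stop_codon_index, full_cds)`` where the index is
    the 1-based codon index of the first stop when it occurs before codon
    ``expected_aa_len + 1`` (before the final codon when no expectation is
    given). ``full_cds`` requires no premature stop and a terminal stop
    codon.
    """
    if len(body) < 6:
        raise ValueError("body too short to contain a CDS")
    if not body.startswith("ATG"):
        raise NoCanonicalStartError("body does not start with ATG")
    n_codons = len(body) // 3
    first_stop = None
    for ci in range(n_codons):
        if body[3 * ci : 3 * ci + 3] in STOP_CODONS:
            first_stop = ci + 1
            break
    limit = expected_aa_len + 1 if expected_aa_len is not None else n_codons
    premature = first_stop if (first_stop is not None and first_stop < limit) else None
    final_is_stop = (
        len(body) % 3 == 0 and body[-3:] in STOP_CODONS and first_stop == n_codons
    )
    full_cds = premature is None and final_is_stop
    return premature, full_cds


def _column_maps(aln: PairwiseAlignment):
    """Per-column positions (or None at gaps) in each ungapped sequence."""
    pos_a, pos_b = [], []
    ia = ib = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        pos_a.append(ia if x != GAP else None)
        pos_b.append(ib if y != GAP else None)
        if x != GAP:
            ia += 1
        if y != GAP:
            ib += 1
    return pos_a, pos_b


def assess_intron_loss(
    body: str,
    parent_mrna: SequenceRecord,
    parent_exon_lengths: Sequence[int],
    min_span: int = 20,
    max_gaps: int = 2,
    min_insert: int = 50,
) -> str:
    """Judge whether the copy lost the parent's introns.

    The copy is aligned to the spliced parent transcript. ``yes`` (introns
    lost) when every exon-exon junction of the parent is spanned colinearly
    by at least ``min_span`` aligned bases containing at most ``max_gaps``
    gap columns; ``no`` when an unaligned genomic insertion of at least
    ``min_insert`` bases coincides with a junction; ``unknown`` when some
    junction has insufficient aligned coverage.
    """
    if sum(parent_exon_lengths) != len(parent_mrna.residues):
        raise ValueError(
            f"exon lengths sum to {sum(parent_exon_lengths)} but parent mRNA "
            f"{parent_mrna.id} has length {len(parent_mrna.residues)}"
        )
    junctions = []
    acc = 0
    for ln in parent_exon_lengths[:-1]:
        acc += ln
        junctions.append(acc)  # position in parent mRNA coordinates
    if not junctions:
        return "unknown"

    aln = global_align(
        SequenceRecord(id="copy", residues=body), parent_mrna
    )
    pos_copy, pos_parent = _column_maps(aln)
    n_cols = aln.n_cols

    # insertion check: maximal runs of parent-gap columns (copy-only sequence)
    runs = []
    start = None
    for c in range(n_cols):
        if pos_parent[c] is None:
            if start is None:
                start = c
        elif start is not None:
            runs.append((start, c))
            start = None
    if start is not None:
        runs.append((start, n_cols))

    def parent_pos_near(col: int) -> Optional[int]:
        for c in range(col, n_cols):
            if pos_parent[c] is not None:
                return pos_parent[c]
        for c in range(col - 1, -1, -1):
            if pos_parent[c] is not None:
                return pos_parent[c] + 1
        return None

    for s, e in runs:
        if e - s >= min_insert:
            at = parent_pos_near(e)
            if at is not None and any(abs(at - j) <= 5 for j in junctions):
                return "no"

    half = min_span // 2 + 2
    for j in junctions:
        cols = [
            c
            for c in range(n_cols)
            if pos_parent[c] is not None and j - half <= pos_parent[c] < j + half
        ]
        if not cols:
            return "unknown"
        lo, hi = min(cols), max(cols) + 1
        aligned = sum(
            1
            for c in range(lo, hi)
            if pos_parent[c] is not None and pos_copy[c] is not None
        )
        gaps = (hi - lo) - aligned
        if aligned < min_span:
            return "unknown"
        if gaps > max_gaps:
            return "no" if gaps >= min_insert else "unknown"
    return "yes"


@dataclass
class ParentCandidate:
    """A candidate parent transcript with its annotated CDS span.

    ``cds_start``/``cds_end`` are 0-based half-open within the mRNA; the 5'
    UTR is ``[0, cds_start)`` and the 3' UTR ``[cds_end, len)``.
    """

    mrna: SequenceRecord
    cds_start: int
    cds_end: int
    exon_lengths: Optional[Sequence[int]] = None

    @property
    def id(self) -> str:
        return self.mrna.id


def _region_identity(
    aln: PairwiseAlignment, pos_b, lo: int, hi: int, min_cover: int = 0
):
    """Identity over the columns where sequence b falls in [lo, hi)."""
    matches = cols = 0
    for c in range(aln.n_cols):
        pb = pos_b[c]
        if pb is None or not (lo <= pb < hi):
            continue
        if aln.aligned_a[c] != GAP:
            cols += 1
            if aln.aligned_a[c] == aln.aligned_b[c]:
                matches += 1
    if cols == 0 or cols < min_cover:
        return None
    return matches / cols


def assign_parent(
    window: RetroWindow,
    candidates: Sequence[ParentCandidate],
    params: Optional[AlignParams] = None,
    min_utr_cover: int = 30,
    recency_identity: float = 0.95,
) -> ParentAssignment:
    """Pick the parent transcript the copy most resembles.

    The whole window (upstream + body + downstream, which contains any
    retained UTR remnants) is globally aligned to each candidate mRNA; the
    winner maximizes identity over the candidate's CDS region. UTR
    identities are reported when at least ``min_utr_cover`` bases align;
    both UTRs at >= ``recency_identity`` flags a recent retrotransposition
    (UTR sequence decays quickly once pseudogenized). Ties break to the
    lexicographically smallest candidate id.
    """
    if not candidates:
        raise ValueError("need at least one parent candidate")
    query = SequenceRecord(
        id=window.locus_id or "query",
        residues=window.upstream + window.body + window.downstream,
    )
    scored = []
    for cand in sorted(candidates, key=lambda c: c.id):
        aln = global_align(query, cand.mrna, params)
        _, pos_b = _column_maps(aln)
        ident_cds = _region_identity(aln, pos_b, cand.cds_start, cand.cds_end)
        if ident_cds is None:
            ident_cds = 0.0
        ident5 = _region_identity(aln, pos_b, 0, cand.cds_start, min_utr_cover)
        ident3 = _region_identity(
            aln, pos_b, cand.cds_end, len(cand.mrna.residues), min_utr_cover
        )
        scored.append((cand, ident_cds, ident5, ident3))
    scored.sort(key=lambda t: (-t[1], t[0].id))
    best, best_cds, best5, best3 = scored[0]
    runner_up = scored[1][1] if len(scored) > 1 else 0.0
    return ParentAssignment(
        best_parent_id=best.id,
        identity_cds=best_cds,
        identity_utr5=best5,
        identity_utr3=best3,
        margin=best_cds - runner_up,
        recency_flag=(
            best5 is not None
            and best3 is not None
            and best5 >= recency_identity
            and best3 >= recency_identity
        ),
        all_identities={c.id: i for c, i, _, _ in scored},
    )


def scan_retrogene(
    window: RetroWindow,
    parent: Optional[ParentCandidate] = None,
    expected_aa_len: Optional[int] = None,
    **detector_kwargs,
) -> RetroFeatureReport:
    """Run all hallmark detectors on one window and compose the verdict.

    ``parent`` (the assigned parent with exon structure) enables the
    intron-loss call and fixes the expected CDS length for the
    premature-stop call; without it intron status is ``unknown`` and the
    copy's own final codon serves as the reference.

    Verdict: ``retrogene`` needs an intact CDS plus at least 3 of the 4
    insertion hallmarks; ``retropseudogene`` needs the same insertion
    evidence with a broken CDS; anything else is ``indeterminate``.
    """
    signal_pos = find_polya_signal(window)
    tail_start = find_polya_tail(window, signal_pos)
    tsd = find_tsd(window, tail_start, **detector_kwargs) if tail_start is not None else None

    if expected_aa_len is None and parent is not None:
        expected_aa_len = (parent.cds_end - parent.cds_start) // 3 - 1
    try:
        premature, full_cds = detect_cds_integrity(window.body, expected_aa_len)
    except NoCanonicalStartError:
        premature, full_cds = None, False

    if parent is not None and parent.exon_lengths is not None:
        lacks_intron = assess_intron_loss(
            window.body, parent.mrna, parent.exon_lengths
        )
    else:
        lacks_intron = "unknown"

    n_hall = sum(
        [
            lacks_intron == "yes",
            signal_pos is not None,
            tail_start is not None,
            tsd is not None,
        ]
    )
    coding_intact = full_cds and premature is None
    if n_hall >= 3:
        verdict = "retrogene" if coding_intact else "retropseudogene"
    else:
        verdict = "indeterminate"
    return RetroFeatureReport(
        locus_id=window.locus_id,
        lacks_intron=lacks_intron,
        polya_signal_pos=signal_pos,
        polya_tail_start=tail_start,
        tsd=tsd,
        premature_stop_codon_index=premature,
        full_cds=full_cds,
        verdict=verdict,
    )


REPORT_COLUMNS = [
    "locus_id",
    "lack_of_intron",
    "polya_signal",
    "polya_signal_pos",
    "polya_tail",
    "polya_tail_start",
    "tsd",
    "tsd_sequence",
    "tsd_length",
    "premature_stop",
    "premature_stop_codon",
    "full_cds",
    "verdict",
]


def report_row(rep: RetroFeatureReport) -> dict:
    """Flatten one report into the hallmark-table TSV row."""
    return {
        "locus_id": rep.locus_id,
        "lack_of_intron": rep.lacks_intron,
        "polya_signal": "yes" if rep.polya_signal_pos is not None else "no",
        "polya_signal_pos": rep.polya_signal_pos,
        "polya_tail": "yes" if rep.polya_tail_start is not None else "no",
        "polya_tail_start": rep.polya_tail_start,
        "tsd": "yes" if rep.tsd is not None else "no",
        "tsd_sequence": rep.tsd.sequence if rep.tsd else None,
        "tsd_length": rep.tsd.length if rep.tsd else None,
        "premature_stop": "yes" if rep.premature_stop_codon_index is not None else "no",
        "premature_stop_codon": rep.premature_stop_codon_index,
        "full_cds": "yes" if rep.full_cds else "no",
        "verdict": rep.verdict,
    }
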