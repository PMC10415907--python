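"""Global pairwise alignment with affine gap penalties.

The identity currency used by parent assignment, chimera scanning and
conservation statistics. The dynamic program is Biopython's PairwiseAligner
(Needleman-Wunsch/Gotoh, C implementation); this module owns the parameter
conventions, the alignment record type and the identity definitions.

Default scores: DNA match=2, mismatch=-3, gap open=-5, gap extend=-2
(EMBOSS-like); protein BLOSUM62 with gap open=-10, extend=-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices

from .seqio import DNA_ALPHABET, GAP, PROTEIN_ALPHABET, AlphabetError, SequenceRecord


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for global alignment.

    ``matrix`` (e.g. "BLOSUM62") overrides match/mismatch for proteins.
    Gap penalties are non-positive; opening a gap of length k costs
    ``gap_open + (k - 1) * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    matrix: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError(
                f"need gap_open <= gap_extend <= 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )


DNA_DEFAULTS = AlignParams()
PROTEIN_DEFAULTS = AlignParams(gap_open=-10.0, gap_extend=-1.0, matrix="BLOSUM62")


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences as equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.aligned_a)

    def matches(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != GAP
        )

    @property
    def identity(self) -> float:
        return percent_identity(self, mode="aligned_columns")


def _guess_alphabet(residues: str) -> str:
    stripped = set(residues) - {GAP}
    if stripped <= DNA_ALPHABET:
        return "dna"
    if stripped <= PROTEIN_ALPHABET:
        return "protein"
    raise AlphabetError(f"unrecognized alphabet in {sorted(stripped)!r}")


def _make_aligner(params: AlignParams, alphabet: str) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if alphabet == "protein" and params.matrix is None:
        # unknown residues (X) under simple scoring behave as mismatches
        pass
    return aligner


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    params: Optional[AlignParams] = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two ungapped sequences.

    The score is the maximum over all global alignments under ``params``;
    the reported alignment is the aligner's deterministic first optimum.
    Raises :class:`AlphabetError` when the two sequences are of different
    molecular type.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    alpha_a, alpha_b = _guess_alphabet(a.residues), _guess_alphabet(b.residues)
    if alpha_a != alpha_b:
        raise AlphabetError(
            f"alphabet mismatch: {a.id} is {alpha_a}, {b.id} is {alpha_b}"
        )
    if params is None:
        params = DNA_DEFAULTS if alpha_a == "dna" else PROTEIN_DEFAULTS
    aligner = _make_aligner(params, alpha_a)
    result = aligner.align(a.residues, b.residues)
    best = result[0]
    return PairwiseAlignment(
        aligned_a=str(best[0]), aligned_b=str(best[1]), score=float(best.score)
    )


def percent_identity(aln: PairwiseAlignment, mode: str = "aligned_columns") -> float:
    """Fraction of identical residues.

    ``aligned_columns``: matches / columns with a residue in both rows
    (end and internal gaps excluded). ``shorter_seq``: matches / length of
    the shorter input.
    """
    matches = aln.matches()
    if mode == "aligned_columns":
        denom = sum(
            1
            for x, y in zip(aln.aligned_a, aln.aligned_b)
            if x != GAP and y != GAP
        )
    elif mode == "shorter_seq":
        denom = min(
            len(aln.aligned_a.replace(GAP, "")),
            len(aln.aligned_b.replace(GAP, "")),
        )
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    if denom == 0:
        raise ZeroDivisionError("identity undefined: no comparable columns")
    return matches / denom


def identity_between(
    a: SequenceRecord, b: SequenceRecord, params: Optional[AlignParams] = None
) -> float:
    """Convenience: align then report aligned-column identity."""
    return percent_identity(global_align(a, b, params))
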