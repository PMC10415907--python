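"""Group profiles, conservation statistics and termini-based classification.

The immunity-related IFITM clade resolves into six groups (IR-pIFITM1/2/3,
-nwm, -owm, -pro) whose members share a nearly invariant central CD225
domain but differ in the sequence and length of their N- and C-termini.
This module turns a per-group alignment into a profile (position weight
matrices over the two terminal blocks plus length ranges), scores query
sequences against competing profiles, and provides the column statistics
the family analysis rests on: fully-conserved-site fractions, numeric
sequence-logo matrices, and consensus-difference calls such as G19R.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import AlignParams, global_align
from .seqio import GAP, Msa, SequenceRecord

PROTEIN_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
DNA_RESIDUES = "ACGT"

GROUP_LABELS = (
    "IR-pIFITM1",
    "IR-pIFITM2",
    "IR-pIFITM3",
    "IR-pIFITMnwm",
    "IR-pIFITMowm",
    "IR-pIFITMpro",
)


def _residues_for(alphabet: str) -> str:
    return DNA_RESIDUES if alphabet == "dna" else PROTEIN_RESIDUES


def conserved_fraction(msa: Msa) -> Tuple[int, int, float]:
    """Count alignment columns that are 100% conserved.

    A column counts as conserved only when every row carries the identical
    residue and no row has a gap (the strictest reading of fully conserved).
    Returns ``(n_conserved, n_columns, fraction)``.
    """
    if msa.n_cols == 0:
        raise ValueError("zero-length alignment")
    n_cons = 0
    for i in range(msa.n_cols):
        col = msa.column(i)
        if GAP not in col and len(set(col)) == 1:
            n_cons += 1
    return n_cons, msa.n_cols, n_cons / msa.n_cols


@dataclass
class LogoMatrix:
    """Numeric sequence logo: per-column residue probabilities and, in
    information mode, per-column information content in bits."""

    residues: str
    probabilities: np.ndarray  # (n_cols, n_residues)
    information: Optional[np.ndarray]  # (n_cols,) bits, or None
    flagged_columns: List[int]  # all-gap columns (probabilities undefined)


def logo_matrix(msa: Msa, mode: str = "probability") -> LogoMatrix:
    """Column-wise residue probabilities, optionally with information content.

    Gaps are excluded from the per-column denominator. Information content
    is ``IC_i = log2(A) + sum_r p_r log2 p_r`` with A the alphabet size and
    no small-sample correction. All-gap columns are flagged and get IC 0.
    """
    if mode not in ("probability", "information"):
        raise ValueError(f"unknown logo mode {mode!r}")
    residues = _residues_for(msa.alphabet)
    idx = {r: k for k, r in enumerate(residues)}
    probs = np.zeros((msa.n_cols, len(residues)))
    flagged = []
    for i in range(msa.n_cols):
        counts = Counter(c for c in msa.column(i) if c != GAP)
        total = sum(counts.values())
        if total == 0:
            flagged.append(i)
            continue
        for r, n in counts.items():
            if r in idx:
                probs[i, idx[r]] = n / total
    info = None
    if mode == "information":
        info = np.zeros(msa.n_cols)
        log_a = math.log2(len(residues))
        for i in range(msa.n_cols):
            if i in flagged:
                continue
            p = probs[i][probs[i] > 0]
            info[i] = log_a + float(np.sum(p * np.log2(p)))
    return LogoMatrix(
        residues=residues, probabilities=probs, information=info, flagged_columns=flagged
    )


def consensus_sequence(msa: Msa) -> SequenceRecord:
    """Per-column majority residue (gaps excluded; ties break alphabetically).
    All-gap columns are dropped."""
    out = []
    for i in range(msa.n_cols):
        counts = Counter(c for c in msa.column(i) if c != GAP)
        if counts:
            out.append(min(counts, key=lambda r: (-counts[r], r)))
    return SequenceRecord(id="consensus", residues="".join(out))


@dataclass
class GroupProfile:
    """Termini signature of one group.

    The PWMs cover the N- and C-terminal alignment blocks with additive
    pseudocounts; the length ranges are the ungapped member lengths within
    those blocks. The consensus locates the blocks on a query via pairwise
    alignment.
    """

    group_label: str
    residues: str
    n_term_pwm: np.ndarray  # (block_cols, n_residues), rows sum to 1
    c_term_pwm: np.ndarray
    n_term_cols: Tuple[int, int]  # half-open column interval in the group MSA
    c_term_cols: Tuple[int, int]
    n_term_len_range: Tuple[int, int]
    c_term_len_range: Tuple[int, int]
    consensus: SequenceRecord
    consensus_colmap: List[Optional[int]]  # MSA column -> consensus position


def _block_pwm(msa: Msa, cols: Tuple[int, int], residues: str, pseudocount: float):
    idx = {r: k for k, r in enumerate(residues)}
    lo, hi = cols
    pwm = np.full((hi - lo, len(residues)), pseudocount)
    for i in range(lo, hi):
        for c in msa.column(i):
            if c in idx:
                pwm[i - lo, idx[c]] += 1
    pwm /= pwm.sum(axis=1, keepdims=True)
    return pwm


def _block_len_range(msa: Msa, cols: Tuple[int, int]) -> Tuple[int, int]:
    lo, hi = cols
    lens = [
        sum(1 for c in rec.residues[lo:hi] if c != GAP) for rec in msa.records
    ]
    return min(lens), max(lens)


def build_group_profile(
    msa: Msa,
    group_label: str,
    n_term_cols: Tuple[int, int],
    c_term_cols: Tuple[int, int],
    pseudocount: float = 0.5,
) -> GroupProfile:
    """Build the termini profile of one group from its member alignment.

    ``n_term_cols`` and ``c_term_cols`` are half-open column intervals in
    the group alignment and must not overlap.
    """
    for lo, hi in (n_term_cols, c_term_cols):
        if not (0 <= lo < hi <= msa.n_cols):
            raise ValueError(f"block {lo, hi} outside alignment of {msa.n_cols} columns")
    if max(n_term_cols[0], c_term_cols[0]) < min(n_term_cols[1], c_term_cols[1]):
        raise ValueError("N- and C-terminal blocks overlap")
    residues = _residues_for(msa.alphabet)
    cons = consensus_sequence(msa)
    colmap: List[Optional[int]] = []
    pos = 0
    for i in range(msa.n_cols):
        col = msa.column(i)
        if any(c != GAP for c in col):
            colmap.append(pos)
            pos += 1
        else:
            colmap.append(None)
    return GroupProfile(
        group_label=group_label,
        residues=residues,
        n_term_pwm=_block_pwm(msa, n_term_cols, residues, pseudocount),
        c_term_pwm=_block_pwm(msa, c_term_cols, residues, pseudocount),
        n_term_cols=n_term_cols,
        c_term_cols=c_term_cols,
        n_term_len_range=_block_len_range(msa, n_term_cols),
        c_term_len_range=_block_len_range(msa, c_term_cols),
        consensus=cons,
        consensus_colmap=colmap,
    )


@dataclass
class Classification:
    group_label: str
    scores: Dict[str, float]  # summed log2 probability per group
    length_flags: Dict[str, Tuple[bool, bool]]  # (n_ok, c_ok) per group
    margin: float
    ambiguous: bool


def _score_against_profile(
    seq: SequenceRecord, profile: GroupProfile, params: Optional[AlignParams]
) -> Tuple[float, Tuple[bool, bool]]:
    aln = global_align(seq, profile.consensus, params)
    # query residue aligned to each consensus position
    cons_to_query: Dict[int, str] = {}
    cp = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if y != GAP:
            cons_to_query[cp] = x  # may be a gap char
            cp += 1
    idx = {r: k for k, r in enumerate(profile.residues)}
    gap_floor = math.log2(0.5 / (len(profile.residues) + 1))
    score = 0.0
    block_lens = []
    for (lo, hi), pwm in (
        (profile.n_term_cols, profile.n_term_pwm),
        (profile.c_term_cols, profile.c_term_pwm),
    ):
        n_res = 0
        for col in range(lo, hi):
            cpos = profile.consensus_colmap[col]
            if cpos is None:
                continue
            ch = cons_to_query.get(cpos, GAP)
            if ch in idx:
                score += math.log2(pwm[col - lo, idx[ch]])
                n_res += 1
            else:
                score += gap_floor
        block_lens.append(n_res)
    n_ok = profile.n_term_len_range[0] - 2 <= block_lens[0] <= profile.n_term_len_range[1] + 2
    c_ok = profile.c_term_len_range[0] - 2 <= block_lens[1] <= profile.c_term_len_range[1] + 2
    return score, (n_ok, c_ok)


def classify_sequence(
    seq: SequenceRecord,
    profiles: Sequence[GroupProfile],
    params: Optional[AlignParams] = None,
) -> Classification:
    """Assign an ungapped sequence to the best-scoring group profile.

    Each profile's terminal blocks are located on the query by global
    alignment to the profile consensus; the score is the summed log2 PWM
    probability over both blocks. Sequences shorter than every profile's
    minimal terminal span are ``indeterminate``. Equal scores break to the
    alphabetically first group label and are flagged ambiguous.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if GAP in seq.residues:
        raise ValueError("query must be ungapped")
    min_span = min(
        p.n_term_len_range[0] + p.c_term_len_range[0] for p in profiles
    )
    if len(seq.residues) < min_span:
        return Classification(
            group_label="indeterminate",
            scores={},
            length_flags={},
            margin=0.0,
            ambiguous=True,
        )
    scores: Dict[str, float] = {}
    flags: Dict[str, Tuple[bool, bool]] = {}
    for prof in sorted(profiles, key=lambda p: p.group_label):
        s, fl = _score_against_profile(seq, prof, params)
        scores[prof.group_label] = s
        flags[prof.group_label] = fl
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_label, best_score = ordered[0]
    runner = ordered[1][1] if len(ordered) > 1 else float("-inf")
    return Classification(
        group_label=best_label,
        scores=scores,
        length_flags=flags,
        margin=best_score - runner,
        ambiguous=math.isclose(best_score, runner, abs_tol=1e-12),
    )


def consensus_diff(
    seq: SequenceRecord,
    consensus: SequenceRecord,
    params: Optional[AlignParams] = None,
) -> List[str]:
    """Substitutions of a sequence relative to a consensus, as e.g. 'G19R'.

    The two sequences are pairwise aligned; every column where both carry a
    residue and they differ yields one entry formatted
    consensus-residue + 1-based consensus position + query residue.
    """
    aln = global_align(seq, consensus, params)
    diffs = []
    cpos = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if y != GAP:
            cpos += 1
            if x != GAP and x != y:
                diffs.append(f"{y}{cpos}{x}")
    return diffs
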