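"""Synteny-based partition of IFITM loci.

Family loci fall into two classes: the canonical cluster — members sitting
on the same contig as the anchor genes PGGHG / B4GALNT4 / CTSD and within a
distance D of their span — and scattered loci elsewhere in the genome, the
retrogene candidates. Scattered loci from different species that share both
flanking genes are grouped (evidence the insertion predates the species
split).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .seqio import GeneLocus

# the paper's "BAGALNT4" spelling is treated as the same anchor
_ANCHOR_ALIASES = {"BAGALNT4": "B4GALNT4"}

DEFAULT_ANCHORS = ("PGGHG", "B4GALNT4", "CTSD")
DEFAULT_MAX_DIST = 500_000  # bp beyond the anchor span still counted as "in cluster"


def _canon_name(name: str) -> str:
    up = name.upper()
    return _ANCHOR_ALIASES.get(up, up)


@dataclass(frozen=True)
class ClusterSpec:
    anchor_genes: Tuple[str, ...] = DEFAULT_ANCHORS
    family_name_pattern: str = "IFITM"
    max_dist: int = DEFAULT_MAX_DIST

    def __post_init__(self) -> None:
        if not self.anchor_genes:
            raise ValueError("need at least one anchor gene")

    def is_family(self, gene_name: str) -> bool:
        return re.search(self.family_name_pattern, gene_name, re.IGNORECASE) is not None

    def is_anchor(self, gene_name: str) -> bool:
        return _canon_name(gene_name) in {_canon_name(a) for a in self.anchor_genes}


@dataclass
class LocusClass:
    locus: GeneLocus
    klass: str  # "canonical" | "scattered"
    intron_resident: bool
    warning: Optional[str] = None


@dataclass
class SyntenyReport:
    classes: List[LocusClass]
    cluster_order: Dict[str, List[Tuple[str, str]]]  # species -> [(gene, strand)]
    shared_flank_groups: List[Set[str]]
    species_warnings: Dict[str, str] = field(default_factory=dict)

    def locus_class(self, locus_id: str) -> str:
        for lc in self.classes:
            if lc.locus.locus_id == locus_id:
                return lc.klass
        raise KeyError(locus_id)

    @property
    def canonical(self) -> List[GeneLocus]:
        return [lc.locus for lc in self.classes if lc.klass == "canonical"]

    @property
    def scattered(self) -> List[GeneLocus]:
        return [lc.locus for lc in self.classes if lc.klass == "scattered"]


def classify_loci(loci: Sequence[GeneLocus], spec: Optional[ClusterSpec] = None) -> SyntenyReport:
    """Partition family loci into canonical-cluster members vs scattered.

    A family locus is canonical iff it lies on the same contig as at least
    one anchor gene and within ``[leftmost anchor - D, rightmost anchor + D]``
    of the anchor span on that contig. A species whose assembly carries no
    anchor at all gets all members classified scattered with a warning
    (mirrors chromosomal rearrangement / assembly-gap cases) rather than an
    error. Classification order is independent of input row order.
    """
    spec = spec or ClusterSpec()
    ordered = sorted(loci, key=lambda lo: (lo.species, lo.contig, lo.start, lo.locus_id))

    # anchor span per (species, contig)
    anchor_span: Dict[Tuple[str, str], Tuple[int, int]] = {}
    species_with_anchor: Set[str] = set()
    for lo in ordered:
        if spec.is_anchor(lo.gene_name):
            key = (lo.species, lo.contig)
            species_with_anchor.add(lo.species)
            if key in anchor_span:
                s, e = anchor_span[key]
                anchor_span[key] = (min(s, lo.start), max(e, lo.end))
            else:
                anchor_span[key] = (lo.start, lo.end)

    classes: List[LocusClass] = []
    species_warnings: Dict[str, str] = {}
    for lo in ordered:
        if not spec.is_family(lo.gene_name):
            continue
        warning = None
        key = (lo.species, lo.contig)
        if lo.species not in species_with_anchor:
            klass = "scattered"
            warning = "no anchor gene found in this species"
            species_warnings[lo.species] = warning
        elif key in anchor_span:
            s, e = anchor_span[key]
            klass = (
                "canonical"
                if (s - spec.max_dist) <= lo.start and lo.end <= (e + spec.max_dist)
                else "scattered"
            )
        else:
            klass = "scattered"
        classes.append(
            LocusClass(
                locus=lo,
                klass=klass,
                intron_resident=lo.host_gene is not None,
                warning=warning,
            )
        )

    report = SyntenyReport(
        classes=classes,
        cluster_order={},
        shared_flank_groups=shared_flank_groups(
            [lc.locus for lc in classes if lc.klass == "scattered"]
        ),
        species_warnings=species_warnings,
    )
    report.cluster_order = cluster_order([lc.locus for lc in classes], report)

    # species with exactly one canonical member are flagged, not adjudicated:
    # single hits may reflect assembly gaps rather than true copy number
    per_species: Dict[str, int] = {}
    for lo in report.canonical:
        per_species[lo.species] = per_species.get(lo.species, 0) + 1
    for sp, n in per_species.items():
        if n == 1:
            report.species_warnings.setdefault(
                sp, "single canonical family member; possible assembly gap"
            )
    return report


def shared_flank_groups(loci: Sequence[GeneLocus]) -> List[Set[str]]:
    """Group scattered loci from different species sharing both flanking genes.

    The (upstream, downstream) pair is compared unordered so opposite-strand
    annotations of the same insertion still match. Singletons are omitted.
    """
    by_pair: Dict[Tuple[str, str], List[GeneLocus]] = {}
    for lo in loci:
        if not lo.upstream_gene or not lo.downstream_gene:
            continue
        pair = tuple(sorted((_canon_name(lo.upstream_gene), _canon_name(lo.downstream_gene))))
        by_pair.setdefault(pair, []).append(lo)
    groups = []
    for pair in sorted(by_pair):
        members = by_pair[pair]
        if len({lo.species for lo in members}) >= 2:
            groups.append({lo.locus_id for lo in members})
    return groups


def cluster_order(
    loci: Sequence[GeneLocus], report: SyntenyReport
) -> Dict[str, List[Tuple[str, str]]]:
    """Per-species order of canonical cluster members with orientation."""
    canonical_ids = {lo.locus_id for lo in report.canonical}
    out: Dict[str, List[Tuple[str, str]]] = {}
    for lo in sorted(loci, key=lambda lo: (lo.species, lo.contig, lo.start)):
        if lo.locus_id in canonical_ids:
            out.setdefault(lo.species, []).append((lo.gene_name, lo.strand))
    return out


SYNTENY_COLUMNS = [
    "locus_id",
    "species",
    "gene_name",
    "class",
    "intron_resident",
    "host_gene",
    "warning",
]


def report_rows(report: SyntenyReport) -> List[dict]:
    """Flatten a SyntenyReport for TSV export (fixed column order)."""
    return [
        {
            "locus_id": lc.locus.locus_id,
            "species": lc.locus.species,
            "gene_name": lc.locus.gene_name,
            "class": lc.klass,
            "intron_resident": "yes" if lc.intron_resident else "no",
            "host_gene": lc.locus.host_gene,
            "warning": lc.warning,
        }
        for lc in report.classes
    ]
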