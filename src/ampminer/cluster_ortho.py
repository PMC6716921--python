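"""Gene-cluster organisation, flanking-marker labelling, naming conventions
and pairwise peptide similarity for ortholog assignment.

Defensin and ovodefensin genes sit in clusters inside one syntenic block:
the ovodefensin cluster is flanked by XKR6 and MTMR9, an intercluster
region (FAM167A, BLK, FDFT1) follows, and CTSB marks the start of the
β-defensin cluster.  Loci are therefore grouped by single-linkage along
each scaffold, labelled by their nearest flanking markers, and named in
order of distance from the anchoring marker (CTSB for defensins, MTMR9 for
ovodefensins), mirroring the published VkBDx_VARKO / VkOVODx_VARKO scheme.

Similarity is computed as pairwise global alignment with free end gaps
(BLOSUM62, gap open 10, extend 0.5); percent identity uses the shorter
ungapped sequence as denominator, which reproduces published
mature-cathelicidin similarity values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import AnnotationRecord

logger = logging.getLogger(__name__)

OVODEFENSIN_MARKER = "MTMR9"
DEFENSIN_MARKER = "CTSB"


@dataclass(frozen=True)
class GeneLocus:
    scaffold_id: str
    start: int                    # 1-based inclusive
    end: int
    strand: str
    peptide_id: str
    gene_class: Literal["defensin", "ovodefensin", "cathelicidin"]

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"locus {self.peptide_id}: start > end")


@dataclass(frozen=True)
class GeneCluster:
    scaffold_id: str
    loci: tuple[GeneLocus, ...]
    left_marker: str | None = None
    right_marker: str | None = None
    label: str = ""
    anomalies: tuple[str, ...] = ()

    @property
    def start(self) -> int:
        return self.loci[0].start

    @property
    def end(self) -> int:
        return max(l.end for l in self.loci)


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    identities: int
    percent_identity: float
    score: float


@dataclass(frozen=True)
class OrthologAssignment:
    query_id: str
    best_reference_id: str | None
    percent_identity: float
    threshold: float

    @property
    def assigned(self) -> bool:
        return self.best_reference_id is not None


def _make_aligner(matrix_name: str, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    # end gaps free: short mature peptides align as colinear overlaps
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:      # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def global_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.5,
                 query_id: str = "query", subject_id: str = "subject"
                 ) -> AlignmentResult:
    """Optimal global alignment with free end gaps; deterministic tie-break
    (Biopython enumerates co-optimal alignments in a fixed order; the first
    is taken)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    best = aligner.align(a, b)[0]
    gapped_a, gapped_b = str(best[0]), str(best[1])
    identities = sum(x == y and x != "-"
                     for x, y in zip(gapped_a, gapped_b))
    pid = round(100.0 * identities / min(len(a), len(b)), 2)
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id,
        aligned_query=gapped_a, aligned_subject=gapped_b,
        identities=identities, percent_identity=pid,
        score=float(best.score))


def percent_identity(a: str, b: str, **kwargs) -> float:
    """Identities over the shorter ungapped length, as a percentage."""
    return global_align(a, b, **kwargs).percent_identity


def assign_orthologs(queries: Sequence, references: Sequence,
                     threshold: float = 40.0) -> list[OrthologAssignment]:
    """Best-hit ortholog naming: highest identity, ties by score then id."""
    if not references:
        logger.warning("empty reference set: all queries unassigned")
        return [OrthologAssignment(q.id, None, 0.0, threshold)
                for q in queries]
    out = []
    for q in queries:
        results = [global_align(q.sequence, r.sequence, query_id=q.id,
                                subject_id=r.id) for r in references]
        results.sort(key=lambda r: (-r.percent_identity, -r.score,
                                    r.subject_id))
        best = results[0]
        if best.percent_identity >= threshold:
            out.append(OrthologAssignment(q.id, best.subject_id,
                                          best.percent_identity, threshold))
        else:
            out.append(OrthologAssignment(q.id, None,
                                          best.percent_identity, threshold))
    return out


def build_clusters(loci: Iterable[GeneLocus],
                   max_gap: int = 100_000) -> list[GeneCluster]:
    """Single-linkage grouping along each scaffold: consecutive loci whose
    inter-locus gap is at most ``max_gap`` bases share a cluster."""
    by_scaffold: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_scaffold.setdefault(locus.scaffold_id, []).append(locus)
    clusters = []
    for scaffold_id in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold_id],
                         key=lambda l: (l.start, l.end, l.peptide_id))
        group = [ordered[0]]
        right = ordered[0].end
        for locus in ordered[1:]:
            if locus.start - right - 1 <= max_gap:
                group.append(locus)
                right = max(right, locus.end)
            else:
                clusters.append(GeneCluster(scaffold_id, tuple(group)))
                group, right = [locus], locus.end
        clusters.append(GeneCluster(scaffold_id, tuple(group)))
    return clusters


def label_clusters(clusters: Sequence[GeneCluster],
                   markers: Sequence[AnnotationRecord]) -> list[GeneCluster]:
    """Attach nearest flanking markers and a defensin/ovodefensin label.

    A marker lying inside a cluster span is recorded as an anomaly, never
    used as a flank.  Clusters adjacent to MTMR9 are labelled
    "ovodefensin-like", to CTSB "defensin-like"; otherwise unlabeled.
    """
    labelled = []
    for cluster in clusters:
        local = [m for m in markers if m.scaffold_id == cluster.scaffold_id]
        inside = [m.name for m in local
                  if m.start <= cluster.end and m.end >= cluster.start]
        lefts = [m for m in local if m.end < cluster.start]
        rights = [m for m in local if m.start > cluster.end]
        left = max(lefts, key=lambda m: m.end).name if lefts else None
        right = min(rights, key=lambda m: m.start).name if rights else None
        flanks = {left, right}
        if OVODEFENSIN_MARKER in flanks:
            label = "ovodefensin-like"
        elif DEFENSIN_MARKER in flanks:
            label = "defensin-like"
        else:
            label = ""
        labelled.append(replace(
            cluster, left_marker=left, right_marker=right, label=label,
            anomalies=tuple(f"marker {name} inside cluster"
                            for name in inside)))
    return labelled


def _marker_position(markers: Sequence[AnnotationRecord],
                     name: str, scaffold_id: str) -> int | None:
    for m in markers:
        if m.name == name and m.scaffold_id == scaffold_id:
            return (m.start + m.end) // 2
    return None


def assign_names(clusters: Sequence[GeneCluster],
                 markers: Sequence[AnnotationRecord],
                 defensin_prefix: str = "VkBD",
                 ovodefensin_prefix: str = "VkOVOD",
                 suffix: str = "_VARKO") -> dict[str, str]:
    """Name loci in marker order: defensins numbered by increasing distance
    from CTSB, ovodefensins from MTMR9; loci on scaffolds without the
    anchoring marker get ordinal names with a scaffold prefix.

    Returns {peptide_id: assigned_name}.
    """
    names: dict[str, str] = {}
    for gene_class, prefix, marker_name in (
            ("defensin", defensin_prefix, DEFENSIN_MARKER),
            ("ovodefensin", ovodefensin_prefix, OVODEFENSIN_MARKER)):
        by_scaffold: dict[str, list[GeneLocus]] = {}
        for cluster in clusters:
            for locus in cluster.loci:
                if locus.gene_class == gene_class:
                    by_scaffold.setdefault(locus.scaffold_id, []).append(locus)
        for scaffold_id in sorted(by_scaffold):
            loci = by_scaffold[scaffold_id]
            anchor = _marker_position(markers, marker_name, scaffold_id)
            if anchor is None:
                ordered = sorted(loci, key=lambda l: (l.start, l.peptide_id))
                for i, locus in enumerate(ordered, start=1):
                    names[locus.peptide_id] = \
                        f"{scaffold_id}_{prefix}{i}{suffix}"
            else:
                ordered = sorted(
                    loci, key=lambda l: (abs((l.start + l.end) // 2 - anchor),
                                         l.peptide_id))
                for i, locus in enumerate(ordered, start=1):
                    names[locus.peptide_id] = f"{prefix}{i}{suffix}"
    return names
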