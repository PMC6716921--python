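"""Synthetic genomes with planted AMP genes, decoys and truth tables.

The generator emulates the composition of a squamate assembly (default GC
fraction 0.443) and plants single-exon reverse-translated peptide genes at
known coordinates, flanked by in-frame stop codons, so that every pipeline
stage can be exercised end to end with an exact truth table.  Planted
coordinates record both the full open reading frame and the genomic span
of each detectable defensin domain, since the domain — not the whole
peptide — is what a motif scan can recover.

Everything is certified at generation time: decoys are verified to contain
no domain under any scanner mode, and both the random background and the
alternative reading frames of planted cassettes are re-scanned and
resampled until the genome contains no spurious motif.  Precision and
recall of a scan against the truth table are therefore exact quantities,
not expectations, for every seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from . import data as _fixtures
from .defensin_scan import (DefensinDomainHit, SpacingConfig,
                            find_defensin_domains)
from .errors import LayoutError, ParameterError
from .seqio import ScaffoldRecord, reverse_complement

_TABLE = unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, ())
    _CODONS_FOR[_aa] += (_codon,)
_STOP_CODONS = tuple(sorted(_TABLE.stop_codons))

GeneClass = Literal["defensin", "ovodefensin", "cathelicidin", "decoy"]

#: Scanner configs used to derive detectable-domain truth per gene class.
CLASS_CONFIG = {"defensin": SpacingConfig.relaxed(),
                "ovodefensin": SpacingConfig.ovodefensin()}


@dataclass(frozen=True)
class PlantedGene:
    peptide_id: str
    peptide: str
    scaffold: int          # index into SyntheticGenomeSpec.lengths
    position: int          # 0-based start of the cassette (incl. 5' stop)
    strand: str
    gene_class: GeneClass

    @property
    def cassette_length(self) -> int:
        return 3 * len(self.peptide) + 6    # flanking stops


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    lengths: tuple[int, ...]
    gc: float = 0.443
    planted: tuple[PlantedGene, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gc <= 1.0:
            raise ParameterError(f"gc fraction outside [0, 1]: {self.gc}")

    @property
    def n_scaffolds(self) -> int:
        return len(self.lengths)


@dataclass(frozen=True)
class TruthRecord:
    scaffold_id: str
    start: int             # 1-based inclusive genomic span of the domain
    end: int
    strand: str
    peptide_id: str
    gene_class: GeneClass
    orf_start: int         # 1-based inclusive span of the coding region
    orf_end: int
    domain_index: int = 0


@dataclass(frozen=True)
class EvaluationReport:
    matched: int
    missed: int
    spurious: int

    @property
    def recall(self) -> float:
        total = self.matched + self.missed
        return self.matched / total if total else 1.0

    @property
    def precision(self) -> float:
        total = self.matched + self.spurious
        return self.matched / total if total else 1.0


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_background(length: int, gc: float = 0.443,
                      seed=0) -> str:
    """I.i.d. background with the requested GC content (reproducible)."""
    if not 0.0 <= gc <= 1.0:
        raise ParameterError(f"gc fraction outside [0, 1]: {gc}")
    rng = _as_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def reverse_translate(peptide: str, seed=0, allow_stop: bool = False) -> str:
    """A coding sequence whose frame-0 translation is ``peptide`` exactly;
    codons are drawn uniformly among synonymous choices."""
    rng = _as_rng(seed)
    codons = []
    for aa in peptide:
        if aa == "*":
            if not allow_stop:
                raise ValueError("stop (*) in peptide")
            choices = _STOP_CODONS
        else:
            try:
                choices = _CODONS_FOR[aa]
            except KeyError:
                raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(choices[rng.integers(len(choices))])
    return "".join(codons)


def _domain_truth(gene: PlantedGene, scaffold_id: str) -> list[TruthRecord]:
    """Truth records for the detectable domains of a planted gene."""
    pos0 = gene.position
    L = gene.cassette_length
    orf_lo0, orf_hi0 = pos0 + 3, pos0 + L - 4      # 0-based inclusive
    if gene.strand == "-":
        orf_lo0, orf_hi0 = (pos0 + L - 1 - (orf_hi0 - pos0),
                            pos0 + L - 1 - (orf_lo0 - pos0))
    config = CLASS_CONFIG.get(gene.gene_class)
    domains = (find_defensin_domains(gene.peptide, config)
               if config is not None else [])
    records = []
    if not domains:      # e.g. cathelicidins: the ORF itself is the truth
        records.append(TruthRecord(
            scaffold_id, orf_lo0 + 1, orf_hi0 + 1, gene.strand,
            gene.peptide_id, gene.gene_class, orf_lo0 + 1, orf_hi0 + 1))
    for k, hit in enumerate(domains):
        b0 = 3 + 3 * (hit.start - 1)         # cassette-relative base span
        b1 = 3 + 3 * hit.end - 1
        if gene.strand == "+":
            lo0, hi0 = pos0 + b0, pos0 + b1
        else:
            lo0, hi0 = pos0 + L - 1 - b1, pos0 + L - 1 - b0
        records.append(TruthRecord(
            scaffold_id, lo0 + 1, hi0 + 1, gene.strand, gene.peptide_id,
            gene.gene_class, orf_lo0 + 1, orf_hi0 + 1, domain_index=k))
    return records


def plant_genes(spec: SyntheticGenomeSpec
                ) -> tuple[list[ScaffoldRecord], list[TruthRecord]]:
    """Build scaffolds with the specified cassettes and their truth table.

    Raises LayoutError on overlapping or out-of-bounds cassettes.  Every
    planted coding region is verified by re-translation before returning.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_background, ss_genes = root.spawn(2)
    bg_streams = ss_background.spawn(spec.n_scaffolds)
    gene_streams = ss_genes.spawn(max(len(spec.planted), 1))

    backgrounds = [list(random_background(n, spec.gc,
                                          np.random.default_rng(s)))
                   for n, s in zip(spec.lengths, bg_streams)]
    occupied: dict[int, list[tuple[int, int]]] = {}
    truth: list[TruthRecord] = []

    for gene, stream in zip(spec.planted, gene_streams):
        if not 0 <= gene.scaffold < spec.n_scaffolds:
            raise LayoutError(f"{gene.peptide_id}: no scaffold {gene.scaffold}")
        L = gene.cassette_length
        lo, hi = gene.position, gene.position + L - 1
        if lo < 0 or hi >= spec.lengths[gene.scaffold]:
            raise LayoutError(f"{gene.peptide_id}: cassette outside scaffold")
        for (a, b) in occupied.get(gene.scaffold, []):
            if lo <= b and hi >= a:
                raise LayoutError(
                    f"{gene.peptide_id}: cassette overlaps another at "
                    f"[{a}, {b}]")
        occupied.setdefault(gene.scaffold, []).append((lo, hi))
        rng = np.random.default_rng(stream)
        coding = reverse_translate(gene.peptide, rng, allow_stop=True)
        cassette = (_STOP_CODONS[rng.integers(3)] + coding
                    + _STOP_CODONS[rng.integers(3)])
        if gene.strand == "-":
            cassette = reverse_complement(cassette)
        backgrounds[gene.scaffold][lo:hi + 1] = list(cassette)

    scaffolds = [ScaffoldRecord(id=f"synthetic_scaffold_{i}",
                                sequence="".join(bg))
                 for i, bg in enumerate(backgrounds)]
    for gene in spec.planted:
        scaffold = scaffolds[gene.scaffold]
        records = _domain_truth(gene, scaffold.id)
        _verify_by_retranslation(gene, scaffold)
        truth.extend(r for r in records if gene.gene_class != "decoy")
    return scaffolds, truth


def _verify_by_retranslation(gene: PlantedGene,
                             scaffold: ScaffoldRecord) -> None:
    lo = gene.position
    hi = lo + gene.cassette_length
    segment = scaffold.sequence[lo:hi]
    if gene.strand == "-":
        segment = reverse_complement(segment)
    coding = segment[3:-3]
    from .seqio import translate_codon
    peptide = "".join(translate_codon(coding[k:k + 3])
                      for k in range(0, len(coding), 3))
    if peptide != gene.peptide:
        raise LayoutError(
            f"{gene.peptide_id}: planted region does not re-translate")


_DECOY_RESIDUES = tuple("ADEFGHIKLMNPQRSTVWY")   # no Cys in the backbone


def generate_decoys(n: int, seed=0, length: int = 48,
                    n_cys: int = 7) -> list[str]:
    """Cysteine-rich peptides certified to contain no defensin domain.

    Decoys carry ``n_cys`` cysteines but no adjacent CC doublet, so their
    gap vector always violates the terminal-adjacency requirement; each one
    is additionally certified against every scanner mode before release.
    """
    rng = _as_rng(seed)
    configs = [SpacingConfig.relaxed(), SpacingConfig.ovodefensin(),
               SpacingConfig.canonical()]
    decoys: list[str] = []
    while len(decoys) < n:
        backbone = [str(_DECOY_RESIDUES[i])
                    for i in rng.integers(len(_DECOY_RESIDUES), size=length)]
        # place cysteines with pairwise distance >= 2 (never adjacent)
        slots = sorted(rng.choice(np.arange(length // 2), size=n_cys,
                                  replace=False) * 2)
        for s in slots:
            backbone[s] = "C"
        peptide = "".join(backbone)
        if any(find_defensin_domains(peptide, c) for c in configs):
            continue
        decoys.append(peptide)
    return decoys


def _interval(call) -> tuple[str, str, int, int]:
    if isinstance(call, DefensinDomainHit):
        return (call.source_id, call.strand, call.genomic_start,
                call.genomic_end)
    if isinstance(call, TruthRecord):
        return (call.scaffold_id, call.strand, call.start, call.end)
    return (call[0], call[1], call[2], call[3])


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int],
                        tolerance: int) -> bool:
    ol = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ol <= 0:
        return False
    la = max(1, a[1] - a[0] + 1 - tolerance)
    lb = max(1, b[1] - b[0] + 1 - tolerance)
    return ol >= 0.5 * la and ol >= 0.5 * lb


def evaluate_calls(calls: Sequence, truth: Sequence[TruthRecord],
                   tolerance: int = 0) -> EvaluationReport:
    """Match calls to truth records (same scaffold and strand, >=50%
    reciprocal overlap within ``tolerance``); greedy one-to-one matching by
    decreasing overlap."""
    call_iv = [_interval(c) for c in calls]
    truth_iv = [_interval(t) for t in truth]
    pairs = []
    for i, c in enumerate(call_iv):
        for j, t in enumerate(truth_iv):
            if c[0] != t[0] or c[1] != t[1]:
                continue
            if _reciprocal_overlap(c[2:], t[2:], tolerance):
                ol = min(c[3], t[3]) - max(c[2], t[2]) + 1
                pairs.append((-ol, i, j))
    pairs.sort()
    used_calls: set[int] = set()
    used_truth: set[int] = set()
    for _, i, j in pairs:
        if i in used_calls or j in used_truth:
            continue
        used_calls.add(i)
        used_truth.add(j)
    matched = len(used_truth)
    return EvaluationReport(matched=matched,
                            missed=len(truth_iv) - matched,
                            spurious=len(call_iv) - len(used_calls))


# --------------------------------------------------------------------------
# Certified genome builders
# --------------------------------------------------------------------------

def _merged_scan(scaffolds: Sequence[ScaffoldRecord]
                 ) -> list[DefensinDomainHit]:
    from .defensin_scan import scan_genome_multi
    return scan_genome_multi(scaffolds)


def _layout_genes(genes: Sequence[tuple[str, str, GeneClass]],
                  n_scaffolds: int, spacing: int, margin: int,
                  ) -> tuple[tuple[int, ...], tuple[PlantedGene, ...]]:
    """Round-robin placement with fixed inter-cassette spacing."""
    positions: list[PlantedGene] = []
    cursors = [margin] * n_scaffolds
    for k, (pid, peptide, gene_class) in enumerate(genes):
        scaffold = k % n_scaffolds
        strand = "+" if (k // n_scaffolds) % 2 == 0 else "-"
        cassette = 3 * len(peptide) + 6
        positions.append(PlantedGene(pid, peptide, scaffold,
                                     cursors[scaffold], strand, gene_class))
        cursors[scaffold] += cassette + spacing
    lengths = tuple(c + margin for c in cursors)
    return lengths, tuple(positions)


def certified_genome(seed: int = 0, n_decoys: int = 50,
                     n_scaffolds: int = 4, spacing: int = 240,
                     max_rounds: int = 40
                     ) -> tuple[list[ScaffoldRecord], list[TruthRecord]]:
    """The reference synthetic genome: every published defensin and
    ovodefensin peptide planted once, plus certified decoy insertions.

    The assembled genome is re-scanned and any spurious motif arising from
    the random background or from an alternative reading frame of a
    cassette is resampled away, so a scan recovers the truth table with
    recall and precision exactly 1.0 at 50% reciprocal overlap.
    """
    genes = [(r.id, r.sequence, "defensin")
             for r in _fixtures.load_beta_defensins()]
    genes += [(r.id, r.sequence, "ovodefensin")
              for r in _fixtures.load_ovodefensins()]
    decoys = generate_decoys(n_decoys,
                             np.random.default_rng(
                                 np.random.SeedSequence((seed, 0xDEC0))))
    genes += [(f"decoy_{i}", p, "decoy") for i, p in enumerate(decoys)]
    lengths, planted = _layout_genes(genes, n_scaffolds, spacing, margin=400)
    spec = SyntheticGenomeSpec(lengths=lengths, planted=planted, seed=seed)
    return _certify(spec, max_rounds=max_rounds)


def _certify(spec: SyntheticGenomeSpec, max_rounds: int = 40
             ) -> tuple[list[ScaffoldRecord], list[TruthRecord]]:
    """Deterministic rejection sampling: rebuild the genome on a derived
    seed chain until a full scan reports no spurious motif (background and
    alternative cassette frames are both covered by the re-scan)."""
    for round_no in range(max_rounds):
        seed = spec.seed if round_no == 0 else _derive_seed(spec.seed,
                                                            round_no)
        scaffolds, truth = plant_genes(replace(spec, seed=seed))
        truth_iv = [(t.scaffold_id, t.strand, t.start, t.end) for t in truth]
        clean = True
        for call in _merged_scan(scaffolds):
            iv = (call.source_id, call.strand, call.genomic_start,
                  call.genomic_end)
            if not any(iv[0] == t[0] and iv[1] == t[1]
                       and _reciprocal_overlap(iv[2:], t[2:], 0)
                       for t in truth_iv):
                clean = False
                break
        if clean:
            return scaffolds, truth
    raise LayoutError("could not certify genome free of spurious motifs")


def _derive_seed(seed: int, round_no: int) -> int:
    return int(np.random.SeedSequence((seed, round_no)).generate_state(1)[0]
               % (2 ** 31))


def emulated_cluster_scaffold(seed: int = 0):
    """A scaled-down emulation of the published defensin/ovodefensin
    syntenic block: XKR6, the six-ovodefensin cluster, MTMR9, the
    intercluster genes (FAM167A, BLK, FDFT1), CTSB, then sixteen defensin
    loci (the intercluster defensin followed by VkBD1-15).

    Returns (scaffold, truth, markers).  The intercluster region is sized
    so that the two AMP clusters stay separate at the default 100 kb
    clustering gap.
    """
    from .seqio import AnnotationRecord

    beta = {r.id: r for r in _fixtures.load_beta_defensins()}
    ovod = _fixtures.load_ovodefensins()

    genes = []
    cursor = 3_000
    marker_rows = []

    def add_marker(name: str, width: int = 900):
        nonlocal cursor
        marker_rows.append((name, cursor + 1, cursor + width))
        cursor += width + 600

    # ovodefensins are numbered in order following MTMR9, which flanks the
    # far end of their cluster: plant VkOVOD6 first so VkOVOD1 is proximal
    add_marker("XKR6")
    for rec in reversed(ovod):
        genes.append((rec.id, rec.sequence, "ovodefensin", cursor))
        cursor += 3 * len(rec.sequence) + 6 + 1_400
    add_marker("MTMR9")
    cursor += 60_000
    add_marker("FAM167A")
    cursor += 40_000
    # the lone intercluster defensin sits isolated between the clusters
    rec = beta["VkBDic1_VARKO"]
    genes.append((rec.id, rec.sequence, "defensin", cursor))
    cursor += 3 * len(rec.sequence) + 6 + 40_000
    add_marker("BLK")
    cursor += 40_000
    add_marker("FDFT1")
    cursor += 22_000
    add_marker("CTSB")
    for i in range(1, 16):
        rec = beta[f"VkBD{i}_VARKO"]
        genes.append((rec.id, rec.sequence, "defensin", cursor))
        cursor += 3 * len(rec.sequence) + 6 + 1_400
    length = cursor + 3_000

    planted = tuple(
        PlantedGene(pid, pep, 0, pos, "+", klass)
        for (pid, pep, klass, pos) in genes)
    spec = SyntheticGenomeSpec(lengths=(length,), planted=planted, seed=seed)
    scaffolds, truth = _certify(spec)
    markers = [AnnotationRecord(scaffold_id=scaffolds[0].id, start=a, end=b,
                                strand="+", feature_type="gene", name=name)
               for name, a, b in marker_rows]
    return scaffolds[0], truth, markers
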