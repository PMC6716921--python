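"""Cathelicidin precursor classification.

A functional cathelicidin precursor carries a conserved N-terminal cathelin
pro-domain with (at least) four cysteines; the mature cationic peptide is
released from the C-terminus by proteolysis.  Because the responsible
protease is unknown, the cleavage site is predicted from sequence context:
in squamate precursors a VRR/VTR-like tripeptide immediately precedes the
mature peptide, within a short window after the last cathelin cysteine.

The classifier applies four rules, in order:

1. at least four cathelin-domain cysteines;
2. a cleavage motif starting within ``window`` residues after the fourth
   cysteine;
3. mature-peptide length within [25, 37] residues;
4. positive integer net charge (His-neutral model) of the mature peptide.

A precursor is accepted only if all four pass.  When no motif is found,
rules 3-4 are still evaluated on the C-terminal 35 residues — the same
fallback a curator applies when judging whether anything antimicrobial
could be hiding at the C-terminus — so rejected precursors report every
failed rule, not just the first.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .properties import ChargeModel, net_charge
from .seqio import ProteinRecord

#: Mature-peptide length range (residues) considered cathelicidin-like.
LENGTH_RANGE = (25, 37)
#: Window length used when no cleavage motif exists (typical mature size).
FALLBACK_TAIL = 35


@dataclass(frozen=True)
class CleavageMotifConfig:
    """Tripeptide motifs marking the predicted cleavage site."""

    motifs: frozenset[str] = frozenset({"VRR", "VTR"})
    pattern: str = "[VIA][TR]R"
    window: int = 10

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not self.motifs and not self.pattern:
            raise ValueError("no motifs configured")

    def matches(self, tripeptide: str) -> bool:
        return tripeptide in self.motifs or (
            bool(self.pattern) and re.fullmatch(self.pattern, tripeptide) is not None)


@dataclass(frozen=True)
class CathelicidinPrecursor:
    id: str
    sequence: str

    @classmethod
    def from_record(cls, record: ProteinRecord) -> "CathelicidinPrecursor":
        return cls(id=record.id, sequence=record.sequence)

    @property
    def cys_positions(self) -> tuple[int, ...]:
        """1-based positions of all cysteines."""
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa == "C")


@dataclass(frozen=True)
class CathelicidinVerdict:
    id: str
    n_cathelin_cys: int
    motif_found: bool
    motif_position: int | None          # 1-based start of the tripeptide
    cterm_peptide: str
    cterm_length: int
    cterm_charge_int: int
    accepted: bool
    reasons: tuple[tuple[str, bool], ...] = field(default_factory=tuple)


def census_cathelin_cys(precursor: CathelicidinPrecursor) -> tuple[int, tuple[int, ...]]:
    """Cysteines up to and including the fourth (the cleavage reference).

    Returns (count, 1-based positions); count < 4 fails the cathelin rule.
    """
    positions = precursor.cys_positions[:4]
    return len(positions), positions


def find_cleavage_motif(precursor: CathelicidinPrecursor,
                        config: CleavageMotifConfig | None = None) -> int | None:
    """1-based start of the first motif within the post-cathelin window.

    The window covers tripeptides whose first residue lies within
    ``config.window`` residues after the fourth cysteine.
    """
    config = config or CleavageMotifConfig()
    n, positions = census_cathelin_cys(precursor)
    if n < 4:
        return None
    anchor = positions[-1]              # 1-based position of 4th cysteine
    seq = precursor.sequence
    for start in range(anchor + 1, min(anchor + config.window,
                                       len(seq) - 2) + 1):
        if config.matches(seq[start - 1: start + 2]):
            return start
    return None


def extract_cterm_peptide(precursor: CathelicidinPrecursor,
                          motif_position: int) -> str:
    """Mature peptide: everything after the cleavage tripeptide."""
    return precursor.sequence[motif_position + 2:]


def classify_precursor(precursor: CathelicidinPrecursor | ProteinRecord,
                       config: CleavageMotifConfig | None = None
                       ) -> CathelicidinVerdict:
    """Apply the four-rule acceptance procedure to one precursor."""
    if isinstance(precursor, ProteinRecord):
        precursor = CathelicidinPrecursor.from_record(precursor)
    config = config or CleavageMotifConfig()

    n_cys, _ = census_cathelin_cys(precursor)
    rule_cys = n_cys >= 4

    motif_pos = find_cleavage_motif(precursor, config) if rule_cys else None
    rule_motif = motif_pos is not None

    if rule_motif:
        peptide = extract_cterm_peptide(precursor, motif_pos)
    else:
        # no predicted cleavage: judge the C-terminal tail instead
        peptide = precursor.sequence[-FALLBACK_TAIL:]

    charge = int(net_charge(peptide, ChargeModel.integer()))
    rule_length = LENGTH_RANGE[0] <= len(peptide) <= LENGTH_RANGE[1]
    rule_charge = charge > 0

    reasons = (
        ("cathelin_cysteines", rule_cys),
        ("cleavage_motif_in_window", rule_motif),
        ("cterm_length_in_range", rule_length),
        ("cterm_net_positive", rule_charge),
    )
    accepted = all(ok for _, ok in reasons)
    return CathelicidinVerdict(
        id=precursor.id,
        n_cathelin_cys=n_cys,
        motif_found=rule_motif,
        motif_position=motif_pos,
        cterm_peptide=peptide if rule_motif else "",
        cterm_length=len(peptide) if rule_motif else 0,
        cterm_charge_int=charge,
        accepted=accepted,
        reasons=reasons,
    )
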