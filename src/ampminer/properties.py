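"""Peptide physicochemistry: length, average molecular weight, net charge
and isoelectric point, in the style of the EMBOSS ``pepstats`` report.

Two charge conventions are used in the antimicrobial-peptide literature and
both appear in published defensin/cathelicidin tables:

* the *half-integer* (pepstats) model — Arg/Lys +1, His +0.5, Asp/Glu −1 —
  which yields the .5-valued charges printed for defensin domains, and
* the *integer* (APD-style) model — His neutral — used for mature
  cathelicidin peptides ("net +12 at physiological pH").

The isoelectric point is the root of the Henderson–Hasselbalch net-charge
curve.  The default pK set below reproduces, to the printed precision, the
pI values of the published Komodo dragon defensin tables this package ships
as golden fixtures (the published values turn out to be *truncated*, not
rounded).  Note the amino-terminus pK of 7.5; with the common 8.6 value the
published table cannot be reproduced.  The set is configuration, not code.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .errors import UndefinedMassError, UndefinedPIError

logger = logging.getLogger(__name__)

#: Average (not monoisotopic) residue masses, Da.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Mass of one water molecule, added once per peptide chain, Da.
WATER_MASS = 18.0153


@dataclass(frozen=True)
class ChargeModel:
    """Fixed per-residue charges (pH-independent by construction)."""

    residue_charge: dict[str, float]
    include_termini: bool = False

    @classmethod
    def half_integer(cls) -> "ChargeModel":
        """pepstats convention: R,K +1; H +0.5; D,E −1."""
        return cls({"R": 1.0, "K": 1.0, "H": 0.5, "D": -1.0, "E": -1.0})

    @classmethod
    def integer(cls) -> "ChargeModel":
        """APD convention: His neutral, everything else as half_integer."""
        return cls({"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0})


POSITIVE_GROUPS = ("Nterm", "K", "R", "H")
NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


@dataclass(frozen=True)
class PKSet:
    """pK values of the ionizable groups used for the pI calculation."""

    pk: dict[str, float] = field(default_factory=lambda: {
        "Nterm": 7.5, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    })
    include_termini: bool = True

    def __post_init__(self):
        for group, value in self.pk.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pK of {group} outside (0, 14): {value}")


DEFAULT_PKSET = PKSet()


@dataclass(frozen=True)
class PeptideProperties:
    """One row of a peptide property report."""

    id: str
    length: int
    molecular_weight: float
    charge_halfint: float
    charge_int: int
    pI: float
    cys_count: int


def molecular_weight(seq: str, on_unknown: str = "raise") -> float:
    """Average molecular weight of a peptide, Da.

    ``on_unknown`` controls residues without a defined mass (X, *):
    "raise" (default) or "skip" (contribute zero; used for pseudogene
    products whose printed sequence contains a premature stop).
    """
    if not seq:
        raise UndefinedMassError("empty sequence has no molecular weight")
    total = WATER_MASS
    for residue in seq:
        try:
            total += AVERAGE_RESIDUE_MASS[residue]
        except KeyError:
            if on_unknown == "raise":
                raise UndefinedMassError(
                    f"residue {residue!r} has no defined mass") from None
            logger.debug("skipping residue %r in molecular weight", residue)
    return total


def net_charge(seq: str, model: ChargeModel | None = None) -> float:
    """Fixed-value net charge; unknown residues contribute 0 (logged)."""
    model = model or ChargeModel.half_integer()
    total = 0.0
    for residue in seq:
        if residue in model.residue_charge:
            total += model.residue_charge[residue]
        elif residue not in AVERAGE_RESIDUE_MASS:
            logger.debug("residue %r carries no charge in this model", residue)
    return total


def _group_counts(seq: str, include_termini: bool) -> dict[str, int]:
    counts = {g: seq.count(g) for g in "KRHDECY"}
    counts["Nterm"] = 1 if include_termini else 0
    counts["Cterm"] = 1 if include_termini else 0
    return counts


def charge_at_pH(seq: str, pH: float, pks: PKSet | None = None) -> float:
    """Henderson–Hasselbalch net charge of the peptide at the given pH."""
    pks = pks or DEFAULT_PKSET
    counts = _group_counts(seq, pks.include_termini)
    charge = 0.0
    for group in POSITIVE_GROUPS:
        n = counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pks.pk[group]))
    for group in NEGATIVE_GROUPS:
        n = counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pks.pk[group] - pH))
    return charge


def isoelectric_point(seq: str, pks: PKSet | None = None) -> float:
    """pH at which the Henderson–Hasselbalch net charge crosses zero.

    Found by root bracketing on [0, 14] to |ΔpH| < 1e-6; the returned pI
    satisfies |charge(pI)| < 1e-4 whenever a sign change exists in range.
    """
    pks = pks or DEFAULT_PKSET
    counts = _group_counts(seq, pks.include_termini)
    if not any(counts.values()):
        raise UndefinedPIError(
            "no ionizable group (termini disabled and no K/R/H/D/E/C/Y)")
    q0, q14 = charge_at_pH(seq, 0.0, pks), charge_at_pH(seq, 14.0, pks)
    if q0 <= 0.0:       # only acidic groups: curve is never positive
        return 0.0
    if q14 >= 0.0:      # only basic groups: curve is never negative
        return 14.0
    return float(brentq(lambda ph: charge_at_pH(seq, ph, pks),
                        0.0, 14.0, xtol=1e-6))


def peptide_report(seq: str, id: str = "", pks: PKSet | None = None,
                   on_unknown: str = "raise") -> PeptideProperties:
    """Full property bundle for one peptide (one report row)."""
    if not seq:
        raise ValueError("empty peptide")
    return PeptideProperties(
        id=id,
        length=len(seq),
        molecular_weight=round(molecular_weight(seq, on_unknown=on_unknown), 2),
        charge_halfint=net_charge(seq, ChargeModel.half_integer()),
        charge_int=int(net_charge(seq, ChargeModel.integer())),
        pI=round(isoelectric_point(seq, pks), 4),
        cys_count=seq.count("C"),
    )


def properties_table(records, pks: PKSet | None = None,
                     on_unknown: str = "raise"):
    """Property report for a list of ProteinRecords as a pandas DataFrame."""
    import pandas as pd

    rows = [peptide_report(r.sequence, id=r.id, pks=pks,
                           on_unknown=on_unknown) for r in records]
    return pd.DataFrame([vars(r) for r in rows]).rename(
        columns={"molecular_weight": "mw"})
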