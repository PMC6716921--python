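"""Packaged fixtures: the published Komodo dragon AMP repertoire.

The FASTA files carry the peptide sequences of the published β-defensin
(66), β-ovodefensin (6) and cathelicidin precursor (3) repertoire; the TSV
files carry the published property values (length, average MW, half-integer
charge, pI) used as golden references by the verification suite.  Rows
whose printed values are internally inconsistent with their own printed
sequence are flagged in the ``anomaly`` column (see docs/methods.md).
"""
from __future__ import annotations

import csv
from importlib import resources

from ..seqio import ProteinRecord


def _data_path(name: str):
    return resources.files("ampminer.data").joinpath(name)


def _load_fasta(name: str) -> list[ProteinRecord]:
    records = []
    current_id, chunks = None, []
    with _data_path(name).open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if current_id is not None:
                    records.append(ProteinRecord(current_id, "".join(chunks)))
                current_id, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if current_id is not None:
        records.append(ProteinRecord(current_id, "".join(chunks)))
    return records


def load_beta_defensins() -> list[ProteinRecord]:
    """The 66 published β-defensin peptides."""
    return _load_fasta("beta_defensins.fasta")


def load_ovodefensins() -> list[ProteinRecord]:
    """The 6 published β-ovodefensin peptides (one a pseudogene with '*')."""
    return _load_fasta("ovodefensins.fasta")


def load_cathelicidin_precursors() -> list[ProteinRecord]:
    """The 3 published cathelicidin precursor proteins."""
    return _load_fasta("cathelicidin_precursors.fasta")


def load_property_table(kind: str) -> list[dict]:
    """Golden property rows; kind is 'beta_defensin' or 'ovodefensin'."""
    name = {"beta_defensin": "beta_defensin_properties.tsv",
            "ovodefensin": "ovodefensin_properties.tsv"}[kind]
    with _data_path(name).open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_cathelicidin_peptide_table() -> list[dict]:
    """Golden mature-cathelicidin rows (peptide, length, charge, MW)."""
    with _data_path("cathelicidin_peptides.tsv").open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
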