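"""Bundled reference catalogues.

The family-template catalogue holds synthetic exemplar precursors for the
eleven toxin families A-K: a signal peptide, an optional propeptide ending
in a processing quadruplet motif, a mature core realizing the family's
cysteine framework, and the family's amidation signal variants. The
exemplars are invented sequences constructed to satisfy the family
definitions (frameworks, propeptide and amidation conventions) — they are
not database sequences. Users can substitute their own panels anywhere a
template list is accepted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

FAMILIES = tuple("ABCDEFGHIJK")

#: relative family sizes of the toxin precursors in the reference study,
#: used as default gene-family weights by the synthetic generator
DEFAULT_FAMILY_COUNTS = {
    "A": 3, "B": 4, "C": 5, "D": 4, "E": 32, "F": 10,
    "G": 14, "H": 10, "I": 3, "J": 5, "K": 8,
}


@dataclass(frozen=True)
class FamilyTemplate:
    family: str
    entry_id: str
    signal: str
    propeptide: str  # "" when the subgroup has none
    mature_core: str
    amid_tails: tuple[str, ...]  # empty when not amidated

    @property
    def has_propeptide(self) -> bool:
        return bool(self.propeptide)

    @property
    def amidated(self) -> bool:
        return bool(self.amid_tails)

    def precursor(self, tail: str | None = None) -> str:
        """Full precursor with one amidation-signal variant appended."""
        if tail is None:
            tail = self.amid_tails[0] if self.amid_tails else ""
        return self.signal + self.propeptide + self.mature_core + tail

    @property
    def n_cys(self) -> int:
        return self.mature_core.count("C")

    @property
    def n_disulfides(self) -> int:
        return self.n_cys // 2


def load_family_templates() -> list[FamilyTemplate]:
    path = resources.files("venomest.data").joinpath("family_templates.tsv")
    with path.open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    templates = []
    for row in rows:
        tails = tuple(t for t in row["amid_tails"].split(",") if t)
        templates.append(
            FamilyTemplate(
                family=row["family"],
                entry_id=row["entry_id"],
                signal=row["signal"],
                propeptide=row["propeptide"],
                mature_core=row["mature_core"],
                amid_tails=tails,
            )
        )
    return templates


_TEMPLATES: list[FamilyTemplate] | None = None


def family_templates() -> list[FamilyTemplate]:
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = load_family_templates()
    return _TEMPLATES


def toxin_panel() -> list[tuple[str, str]]:
    """(id, full precursor) pairs for homology categorisation."""
    return [(t.entry_id, t.precursor()) for t in family_templates()]


def mature_template_panel() -> list[tuple[str, str, str]]:
    """(family, entry_id, mature core) triples for family classification."""
    return [(t.family, t.entry_id, t.mature_core) for t in family_templates()]


def cellular_panel() -> list[tuple[str, str]]:
    """Synthetic housekeeping-like proteins for the cellular category."""
    path = resources.files("venomest.data").joinpath("cellular_panel.fasta")
    with path.open() as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
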