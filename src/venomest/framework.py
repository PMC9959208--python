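"""Cysteine frameworks, disulfide scaffolds, and family classification.

The cysteine framework of a mature peptide is the ordered list of its
cysteine positions, written C1..Cn with a hyphen between consecutive
cysteines except when they are immediately adjacent in the sequence (zero
intervening residues), in which case the tokens are concatenated
("C3C4"). Frameworks index a catalogue of disulfide scaffolds whose
connectivities are assigned by similarity to characterised folds (ICK, DDH,
Kunitz, and family-specific extensions) — never predicted de novo.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .annotate import align_protein


@dataclass(frozen=True)
class CysteineFramework:
    positions: tuple[int, ...]
    notation: str

    @property
    def n_cys(self) -> int:
        return len(self.positions)

    @property
    def adjacency(self) -> frozenset[int]:
        """1-based indices i such that C_i and C_{i+1} are sequence-adjacent."""
        return frozenset(
            i + 1
            for i in range(len(self.positions) - 1)
            if self.positions[i + 1] - self.positions[i] == 1
        )


def extract_framework(mature: str) -> CysteineFramework:
    """Framework of a mature peptide (empty notation when cysteine-free)."""
    if not mature:
        raise ValueError("empty mature peptide")
    positions = tuple(i for i, a in enumerate(mature) if a == "C")
    return CysteineFramework(positions=positions, notation=_notation(positions))


def _notation(positions: Sequence[int]) -> str:
    parts: list[str] = []
    for i in range(len(positions)):
        token = f"C{i + 1}"
        if i > 0 and positions[i] - positions[i - 1] > 1:
            parts.append("-")
        parts.append(token)
    return "".join(parts)


_TOKEN = re.compile(r"C(\d+)")


def parse_notation(notation: str) -> CysteineFramework:
    """Parse a framework string back into canonical cysteine positions.

    Positions are reconstructed with one spacer residue per hyphen, which
    preserves the adjacency structure (the round-trip invariant is on the
    notation, not on absolute spacing).
    """
    if notation == "":
        return CysteineFramework(positions=(), notation="")
    pos = 0
    positions: list[int] = []
    expected = 1
    for chunk in notation.split("-"):
        tokens = _TOKEN.findall(chunk)
        if not tokens or _TOKEN.sub("", chunk):
            raise ValueError(f"bad framework notation: {notation!r}")
        for t in tokens:
            if int(t) != expected:
                raise ValueError(f"non-sequential token C{t} in {notation!r}")
            positions.append(pos)
            pos += 1
            expected += 1
        pos += 1  # hyphen = at least one spacer residue
    return CysteineFramework(positions=tuple(positions), notation=_notation(positions))


@dataclass(frozen=True)
class ScaffoldEntry:
    motif_name: str
    n_cys: int
    adjacency: frozenset[int]
    disulfide_pairs: frozenset[tuple[int, int]] | None
    description: str = ""


def _parse_pairs(text: str) -> frozenset[tuple[int, int]] | None:
    if not text:
        return None
    pairs = []
    for part in text.split(","):
        a, b = part.split("-")
        pairs.append((int(a), int(b)))
    return frozenset(pairs)


def load_scaffold_catalogue() -> list[ScaffoldEntry]:
    with resources.files("venomest.data").joinpath("scaffolds.tsv").open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    entries = []
    for row in rows:
        adjacency = frozenset(
            int(x) for x in row["adjacency"].split(",") if x.strip()
        )
        entries.append(
            ScaffoldEntry(
                motif_name=row["motif"],
                n_cys=int(row["n_cys"]),
                adjacency=adjacency,
                disulfide_pairs=_parse_pairs(row["pairs"]),
                description=row.get("description", ""),
            )
        )
    return entries


_CATALOGUE: list[ScaffoldEntry] | None = None


def scaffold_catalogue() -> list[ScaffoldEntry]:
    global _CATALOGUE
    if _CATALOGUE is None:
        _CATALOGUE = load_scaffold_catalogue()
    return _CATALOGUE


UNASSIGNED_SCAFFOLD = ScaffoldEntry(
    motif_name="unassigned", n_cys=0, adjacency=frozenset(), disulfide_pairs=None
)


def assign_scaffold(
    framework: CysteineFramework, motif_hint: str | None = None
) -> ScaffoldEntry:
    """Match a framework against the scaffold catalogue.

    Matching is exact on cysteine count and adjacency mask. Some patterns
    are shared by several folds (DDH and Kunitz both have six non-adjacent
    cysteines); ``motif_hint`` selects among the matches, otherwise the
    first catalogue entry wins. No match returns the unassigned scaffold.
    """
    matches = [
        e
        for e in scaffold_catalogue()
        if e.n_cys == framework.n_cys and e.adjacency == framework.adjacency
    ]
    if motif_hint is not None:
        matches = [e for e in matches if e.motif_name == motif_hint]
    if not matches:
        return UNASSIGNED_SCAFFOLD
    return matches[0]


@dataclass(frozen=True)
class FamilyAssignment:
    family: str  # 'A'..'K' or 'unassigned'
    evidence: frozenset[str] = field(default_factory=frozenset)
    template_id: str = ""
    identity_pct: float = 0.0


def _framework_compatible(
    framework: CysteineFramework, template_fw: CysteineFramework
) -> bool:
    """Exact framework match, or one cysteine short of the template.

    The one-cysteine tolerance mirrors natural single-site cysteine losses
    (a framework member with one cysteine mutated away stays in its family).
    """
    if (
        framework.n_cys == template_fw.n_cys
        and framework.adjacency == template_fw.adjacency
    ):
        return True
    return framework.n_cys == template_fw.n_cys - 1


def classify_family(
    mature_peptide: str,
    framework: CysteineFramework,
    family_templates: Sequence[tuple[str, str, str]],
    min_identity_pct: float = 60.0,
    min_cov_pct: float = 60.0,
) -> FamilyAssignment:
    """Assign a family letter from framework compatibility plus homology.

    ``family_templates`` are (family_letter, template_id, mature_seq)
    exemplars. Candidates are templates whose framework is compatible with
    the query's; the winner is the candidate with the highest mature-peptide
    identity at or above ``min_identity_pct`` (with adequate coverage).
    Queries with cysteines but no qualifying candidate fall into the
    low-homology catch-all family K; cysteine-poor queries stay unassigned.
    """
    if not family_templates:
        raise ValueError("empty family template set")
    best: FamilyAssignment | None = None
    for fam, tid, tmature in family_templates:
        tfw = extract_framework(tmature)
        if not _framework_compatible(framework, tfw):
            continue
        ident, cov, _score = align_protein(mature_peptide, tmature)
        if ident < min_identity_pct or cov < min_cov_pct:
            continue
        evidence = frozenset({"framework-match", "homology-best-hit"})
        cand = FamilyAssignment(fam, evidence, tid, ident)
        if best is None or cand.identity_pct > best.identity_pct:
            best = cand
    if best is not None:
        return best
    if framework.n_cys >= 2:
        return FamilyAssignment("K", frozenset({"identity-cluster"}), "", 0.0)
    return FamilyAssignment("unassigned")
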