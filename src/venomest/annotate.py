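"""Translated homology annotation of ESTs.

Each trimmed EST is translated in all six frames; maximal open reading
frames are scored by Smith-Waterman local alignment (BLOSUM62, affine gaps)
against two bundled protein panels — toxin exemplars and housekeeping-like
cellular proteins — and the EST is assigned to one of three categories:
``toxin-like``, ``cellular``, or ``non-matched``.

Coordinates are 0-based half-open. Frames follow the BLAST convention:
+1/+2/+3 on the given strand, -1/-2/-3 on the reverse complement, the digit
being the phase offset plus one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import biotite.sequence as bseq
import biotite.sequence.align as balign

from ._tables import CODON_TABLE
from .qc import ESTRecord

TOXIN = "toxin-like"
CELLULAR = "cellular"
NON_MATCHED = "non-matched"

FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a coding-strand nucleotide string (standard code).

    Trailing partial codons are ignored; stop codons appear as ``*``.
    """
    return "".join(
        CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


@dataclass(frozen=True)
class OrfCall:
    """A maximal open reading frame on one strand/phase of an EST.

    ``cds_start``/``cds_end`` are nucleotide coordinates on the reading
    strand (the reverse complement for negative frames); the CDS includes
    the stop codon when ``has_stop``.
    """

    frame: int
    cds_start: int
    cds_end: int
    protein: str
    has_start: bool
    has_stop: bool

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


def six_frame_orfs(est: ESTRecord | str, min_codons: int = 30) -> list[OrfCall]:
    """All maximal ORFs of at least ``min_codons`` codons in six frames.

    A maximal ORF is a stop-free codon run bounded by stop codons or the
    sequence ends; ``has_start`` records whether its first codon is ATG.
    """
    seq = est.trimmed_seq if isinstance(est, ESTRecord) else est
    seq = seq.upper()
    if len(seq) < 3:
        return []
    orfs: list[OrfCall] = []
    rc = revcomp(seq)
    for frame in FRAMES:
        strand_seq = seq if frame > 0 else rc
        phase = abs(frame) - 1
        n_codons = (len(strand_seq) - phase) // 3
        if n_codons <= 0:
            continue
        aa = translate(strand_seq[phase : phase + 3 * n_codons])
        start = 0
        for i, ch in enumerate(aa + "*"):
            if ch != "*":
                continue
            seg = aa[start:i]
            has_stop = i < len(aa)
            if len(seg) >= min_codons:
                cds_start = phase + 3 * start
                cds_end = phase + 3 * (i + 1 if has_stop else i)
                orfs.append(
                    OrfCall(
                        frame=frame,
                        cds_start=cds_start,
                        cds_end=min(cds_end, len(strand_seq)),
                        protein=seg,
                        has_start=strand_seq[cds_start : cds_start + 3] == "ATG",
                        has_stop=has_stop,
                    )
                )
            start = i + 1
    return orfs


def best_orf(orfs: Sequence[OrfCall]) -> OrfCall:
    """Longest-protein ORF; ties prefer ATG starts, then frame order, then 5'."""
    if not orfs:
        raise ValueError("no ORF")
    return min(
        orfs,
        key=lambda o: (
            -len(o.protein),
            not o.has_start,
            FRAMES.index(o.frame),
            o.cds_start,
        ),
    )


@dataclass(frozen=True)
class HomologyHit:
    subject_id: str
    panel: str
    identity_pct: float
    query_cov_pct: float
    score: int


@dataclass(frozen=True)
class CategoryCall:
    category: str
    best_hit: HomologyHit | None
    reason: str = ""


@lru_cache(maxsize=1)
def _blosum62() -> balign.SubstitutionMatrix:
    return balign.SubstitutionMatrix.std_protein_matrix()


def align_protein(query: str, subject: str) -> tuple[float, float, int]:
    """Local protein alignment (BLOSUM62, gap open 11 / extend 1).

    The opening penalty is charged on the first gapped column and the
    extension on each subsequent one. Returns
    ``(identity_pct, query_cov_pct, score)`` where identity is over aligned
    columns and coverage is the fraction of query residues in the alignment.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    q = bseq.ProteinSequence(query)
    s = bseq.ProteinSequence(subject)
    aln = balign.align_optimal(
        q, s, _blosum62(), gap_penalty=(-11, -1), local=True, max_number=1
    )[0]
    trace = aln.trace
    if len(trace) == 0:
        return 0.0, 0.0, 0
    matches = sum(
        1
        for qi, si in trace
        if qi != -1 and si != -1 and query[qi] == subject[si]
    )
    identity_pct = 100.0 * matches / len(trace)
    aligned_query = sum(1 for qi, _ in trace if qi != -1)
    query_cov_pct = 100.0 * aligned_query / len(query)
    return identity_pct, query_cov_pct, int(aln.score)


def _protein_kmers(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


class PanelIndex:
    """A reference protein panel with a shared-k-mer alignment prescreen.

    A subject is only aligned when it shares at least one exact amino-acid
    k-mer with the query, which prunes the all-ORFs x all-subjects scan to
    the genuinely homologous pairs. ``k=None`` disables the prescreen.
    """

    def __init__(self, name: str, entries: Sequence[tuple[str, str]], k: int | None = 4):
        self.name = name
        self.entries = list(entries)
        self.k = k
        self._kmers = (
            [_protein_kmers(seq, k) for _, seq in self.entries] if k else None
        )

    @classmethod
    def ensure(
        cls, panel: "PanelIndex | Sequence[tuple[str, str]]", name: str
    ) -> "PanelIndex":
        return panel if isinstance(panel, PanelIndex) else cls(name, panel)

    def best_hit(self, query: str) -> HomologyHit | None:
        qk = _protein_kmers(query, self.k) if self.k else None
        best: HomologyHit | None = None
        for i, (sid, sseq) in enumerate(self.entries):
            if qk is not None and qk.isdisjoint(self._kmers[i]):
                continue
            ident, cov, score = align_protein(query, sseq)
            if best is None or score > best.score:
                best = HomologyHit(sid, self.name, ident, cov, score)
        return best


def categorize(
    est: ESTRecord,
    toxin_panel: "PanelIndex | Sequence[tuple[str, str]]",
    cellular_panel: "PanelIndex | Sequence[tuple[str, str]]",
    min_identity_pct: float = 40.0,
    min_cov_pct: float = 50.0,
    min_codons: int = 30,
) -> tuple[CategoryCall, OrfCall | None]:
    """Assign an EST to toxin-like / cellular / non-matched.

    Every ORF is searched against both panels (the translated search spans
    all six frames, the way a blastx-style annotation does); the
    highest-scoring hit passing both the identity and the coverage
    threshold decides the category, with the toxin panel winning score
    ties. The returned ORF is the one carrying the deciding hit — the
    reading frame of the precursor for a true toxin cDNA — or the longest
    ORF when nothing passes. ESTs without an ORF of at least ``min_codons``
    codons are non-matched with reason "no-orf".
    """
    tox = PanelIndex.ensure(toxin_panel, "toxin")
    cell = PanelIndex.ensure(cellular_panel, "cellular")
    if not tox.entries or not cell.entries:
        raise ValueError("reference panels must be non-empty")
    orfs = six_frame_orfs(est, min_codons=min_codons)
    if not orfs:
        return CategoryCall(NON_MATCHED, None, reason="no-orf"), None
    best: HomologyHit | None = None
    best_orf_for_hit: OrfCall | None = None
    for orf in orfs:
        for panel in (tox, cell):
            hit = panel.best_hit(orf.protein)
            if (
                hit is None
                or hit.identity_pct < min_identity_pct
                or hit.query_cov_pct < min_cov_pct
            ):
                continue
            if best is None or (hit.score, hit.panel == "toxin") > (
                best.score, best.panel == "toxin"
            ):
                best = hit
                best_orf_for_hit = orf
    if best is None:
        return CategoryCall(NON_MATCHED, None, reason="below-threshold"), best_orf(orfs)
    category = TOXIN if best.panel == "toxin" else CELLULAR
    return CategoryCall(category, best), best_orf_for_hit
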