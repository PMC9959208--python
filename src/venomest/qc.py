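"""EST quality control and I/O.

A sequenced cDNA clone insert qualifies as a high-quality EST when its raw
length is strictly greater than the configured cutoff (default 300 nt).
Library-derived ESTs carry a 3' poly-A tail which is detected and trimmed
before any downstream translation or clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

#: record origins
LIBRARY = "library"
TRANSCRIPTOMIC = "transcriptomic"


@dataclass(frozen=True)
class ESTRecord:
    """One quality-controlled cDNA sequence.

    ``trimmed_seq`` is the sequence after poly-A removal; ``polya_len`` is the
    number of trimmed tail bases. ``len(trimmed_seq) + polya_len <= len(seq)``
    always holds (equality unless the record was not yet tail-trimmed).
    """

    id: str
    seq: str
    origin: str = LIBRARY
    polya_len: int = 0
    trimmed_seq: str = field(default="")
    tail_only: bool = False

    def __post_init__(self) -> None:
        if not self.trimmed_seq and self.polya_len == 0:
            object.__setattr__(self, "trimmed_seq", self.seq)

    @property
    def raw_length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Rejection:
    id: str
    reason: str


def read_fasta(path: str | Path, origin: str = LIBRARY) -> list[ESTRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ESTRecord(id=rec.id, seq=str(rec.seq).upper(), origin=origin))
    return records


def write_fasta(records: Iterable[ESTRecord], path: str | Path, trimmed: bool = False) -> None:
    seqs = [
        SeqRecord(Seq(r.trimmed_seq if trimmed else r.seq), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def qc_filter(
    records: Iterable[ESTRecord],
    min_len_exclusive: int = 300,
    max_n_fraction: float = 0.05,
) -> tuple[list[ESTRecord], list[Rejection]]:
    """Keep records whose raw length is > ``min_len_exclusive``.

    A 301-nt insert is the shortest kept sequence under the default cutoff.
    Records with characters outside A/C/G/T/N are rejected with reason
    "alphabet"; records with more than ``max_n_fraction`` ambiguous bases with
    reason "ambiguous".
    """
    if min_len_exclusive < 0:
        raise ValueError("min_len_exclusive must be >= 0")
    kept: list[ESTRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        seq = rec.seq.upper()
        if set(seq) - VALID_ALPHABET:
            rejected.append(Rejection(rec.id, "alphabet"))
            continue
        if len(seq) > 0 and seq.count("N") / len(seq) > max_n_fraction:
            rejected.append(Rejection(rec.id, "ambiguous"))
            continue
        if len(seq) <= min_len_exclusive:
            rejected.append(Rejection(rec.id, "length"))
            continue
        kept.append(rec if rec.seq == seq else replace(rec, seq=seq, trimmed_seq=seq))
    return kept, rejected


def detect_polya(seq: str, min_run: int = 10, max_mismatch: int = 1) -> tuple[int, str]:
    """Detect the longest 3'-terminal poly-A run allowing a few mismatches.

    Returns ``(polya_len, trimmed_seq)``. Scanning from the 3' end, the tail
    is extended while at most ``max_mismatch`` non-A bases have been crossed;
    the tail ends at the last A before the mismatch budget is exceeded. Runs
    shorter than ``min_run`` are not treated as tails.
    """
    if not seq:
        raise ValueError("empty sequence")
    mismatches = 0
    tail_start = len(seq)  # index where the accepted tail begins
    i = len(seq) - 1
    while i >= 0:
        if seq[i] == "A":
            tail_start = i
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
        i -= 1
    polya_len = len(seq) - tail_start
    if polya_len < min_run:
        return 0, seq
    return polya_len, seq[:tail_start]


def trim_polya(rec: ESTRecord, min_run: int = 10, max_mismatch: int = 1) -> ESTRecord:
    """Trim the 3' poly-A tail of a record, iterating to a fixpoint.

    Iteration matters when the tail contains interior mismatches: a single
    detection pass can leave a residual terminal A-run, and the contract is
    that re-detection on the trimmed sequence finds nothing.
    """
    total = 0
    trimmed = rec.seq
    while trimmed:
        polya_len, trimmed2 = detect_polya(trimmed, min_run=min_run, max_mismatch=max_mismatch)
        if polya_len == 0:
            break
        total += polya_len
        trimmed = trimmed2
    return replace(
        rec,
        polya_len=total,
        trimmed_seq=trimmed,
        tail_only=(total > 0 and not trimmed),
    )


def merge_sources(
    library: Iterable[ESTRecord], transcriptomic: Iterable[ESTRecord]
) -> tuple[list[ESTRecord], list[tuple[str, str]]]:
    """Pool library and transcriptomic ESTs, tagging origins.

    Identical trimmed sequences appearing in both sources are kept as
    separate records but reported as cross-references (deduplication only
    happens later at the protein level). Duplicate ids across sources are an
    error.
    """
    lib = [replace(r, origin=LIBRARY) if r.origin != LIBRARY else r for r in library]
    tx = [
        replace(r, origin=TRANSCRIPTOMIC) if r.origin != TRANSCRIPTOMIC else r
        for r in transcriptomic
    ]
    lib_ids = {r.id for r in lib}
    collisions = lib_ids & {r.id for r in tx}
    if collisions:
        raise ValueError(f"id collision: {sorted(collisions)[:5]}")
    by_seq: dict[str, str] = {r.trimmed_seq: r.id for r in lib}
    cross_refs = [
        (by_seq[r.trimmed_seq], r.id) for r in tx if r.trimmed_seq in by_seq
    ]
    return lib + tx, cross_refs
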