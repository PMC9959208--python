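"""Toxin precursor segmentation and peptide masses.

A secreted spider-toxin precursor is signal peptide -> optional propeptide
-> mature peptide. The signal peptide is called by a hydrophobicity
heuristic with the classic small-residue constraint at the -1/-3 positions
of the cleavage site; the propeptide ends at a processing quadruplet motif
(PQM): a four-residue window ending in arginine that carries at least one
glutamate in its first three positions, cleavage occurring immediately
after the arginine. A C-terminal -G / -GK / -GGK on the pre-processing
mature region is an amidation signal: the terminal glycine is converted to
a C-terminal amide (losing 0.984016 Da) during maturation.

All amino-acid coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._tables import (
    AMIDATION_AVG,
    AMIDATION_MONO,
    AVG_RESIDUE,
    DISULFIDE_AVG,
    DISULFIDE_MONO,
    KYTE_DOOLITTLE,
    MONO_RESIDUE,
    SMALL_RESIDUES,
    WATER_AVG,
    WATER_MONO,
)

MIN_CLEAVAGE = 15
MAX_CLEAVAGE = 35
HYDROPATHY_WINDOW = 8
MIN_CORE_HYDROPATHY = 1.5


@dataclass(frozen=True)
class Precursor:
    """A segmented toxin precursor."""

    name: str
    full_seq: str
    signal: tuple[int, int] | None
    propeptide: tuple[int, int] | None
    mature: tuple[int, int]
    mature_peptide: str  # post-processing (amidation signal removed)
    amidated: bool
    partial_n_terminus: bool
    origin: str = "library"
    c_terminus_complete: str = "yes"  # yes / no / unknown


def call_signal_peptide(seq: str) -> int | None:
    """Predict the signal-peptidase cleavage position, or None.

    Candidate cleavage positions p in [15, 35] are scored by the mean
    Kyte-Doolittle hydropathy of the 8 residues preceding position -5
    (``seq[p-13:p-5]``); a candidate qualifies only if that mean is >= 1.5
    and the residues at -1 and -3 are small (A/G/S/C/T). The
    highest-scoring site wins, earlier position on ties. Sequences not
    starting with M (or shorter than 18 aa) get no call.
    """
    if len(seq) < 18 or not seq.startswith("M"):
        return None
    best_p, best_score = None, None
    for p in range(MIN_CLEAVAGE, min(MAX_CLEAVAGE, len(seq) - 1) + 1):
        if seq[p - 1] not in SMALL_RESIDUES or seq[p - 3] not in SMALL_RESIDUES:
            continue
        window = seq[p - 13 : p - 5]
        score = sum(KYTE_DOOLITTLE.get(a, 0.0) for a in window) / len(window)
        if score < MIN_CORE_HYDROPATHY:
            continue
        if best_score is None or score > best_score:
            best_p, best_score = p, score
    return best_p


def is_pqm(quad: str) -> bool:
    """True if a 4-residue window is a processing quadruplet motif."""
    return len(quad) == 4 and quad[3] == "R" and "E" in quad[:3]


def call_propeptide(seq_after_signal: str) -> int | None:
    """Position where the propeptide ends (mature starts), or None.

    Scans for PQM windows whose arginine precedes the first cysteine and
    returns the cleavage after the last such site. Without cysteines the
    whole sequence is scanned.
    """
    first_c = seq_after_signal.find("C")
    limit = first_c if first_c != -1 else len(seq_after_signal)
    best = None
    for i in range(4, limit + 1):
        if is_pqm(seq_after_signal[i - 4 : i]):
            best = i
    return best


def apply_amidation(mature_candidate: str) -> tuple[str, bool]:
    """Strip a C-terminal amidation signal (-G, -GK or -GGK).

    At most one trailing lysine is removed, then one terminal glycine; the
    glycine marks the amide donor, so its removal sets the amidated flag.
    """
    if not mature_candidate:
        raise ValueError("degenerate mature")
    seq = mature_candidate
    if seq.endswith("K"):
        seq = seq[:-1]
    if seq.endswith("G"):
        seq = seq[:-1]
        if not seq:
            raise ValueError("degenerate mature")
        return seq, True
    return mature_candidate, False


def assign_name(
    serial: int,
    partial: bool = False,
    transcriptomic: bool = False,
    prefix: str = "LcTx",
) -> str:
    """Toxin naming: <prefix>-<serial>, then -P for partial, -T for transcriptomic."""
    if serial < 1:
        raise ValueError("serial must be >= 1")
    name = f"{prefix}-{serial}"
    if partial:
        name += "-P"
    if transcriptomic:
        name += "-T"
    return name


def segment_precursor(
    protein: str,
    name: str = "",
    origin: str = "library",
    has_start: bool = True,
    has_stop: bool = True,
) -> Precursor:
    """Segment a translated precursor into signal / propeptide / mature.

    Sequences without a recognizable initiator methionine signal peptide are
    flagged N-terminally partial; their whole sequence is treated as the
    mature candidate (signal and propeptide unresolvable).
    """
    cleavage = call_signal_peptide(protein) if has_start else None
    partial = cleavage is None
    if partial:
        signal = None
        propep = None
        mature_start = 0
    else:
        signal = (0, cleavage)
        after = protein[cleavage:]
        pro_end = call_propeptide(after)
        if pro_end is None:
            propep = None
            mature_start = cleavage
        else:
            propep = (cleavage, cleavage + pro_end)
            mature_start = cleavage + pro_end
    mature_region = protein[mature_start:]
    if has_stop and mature_region:
        mature_peptide, amidated = apply_amidation(mature_region)
    else:
        mature_peptide, amidated = mature_region, False
    return Precursor(
        name=name,
        full_seq=protein,
        signal=signal,
        propeptide=propep,
        mature=(mature_start, len(protein)),
        mature_peptide=mature_peptide,
        amidated=amidated,
        partial_n_terminus=partial,
        origin=origin,
        c_terminus_complete="yes" if has_stop else "unknown",
    )


@dataclass(frozen=True)
class PeptideMass:
    monoisotopic_da: float
    average_da: float
    n_disulfides: int
    amidated: bool


def peptide_mass(mature: str, n_disulfides: int = 0, amidated: bool = False) -> PeptideMass:
    """Neutral peptide mass from the additive residue-mass formula.

    monoisotopic = sum(residues) + water - 2 * 1.007825 * n_disulfides
    - 0.984016 if amidated; the average mass uses average-mass tables.
    """
    bad = sorted(set(mature) - set(MONO_RESIDUE))
    if bad:
        raise ValueError(f"non-standard residues: {''.join(bad)}")
    if not mature:
        raise ValueError("empty peptide")
    if 2 * n_disulfides > mature.count("C"):
        raise ValueError("more disulfides than cysteine pairs")
    mono = sum(MONO_RESIDUE[a] for a in mature) + WATER_MONO
    avg = sum(AVG_RESIDUE[a] for a in mature) + WATER_AVG
    mono -= DISULFIDE_MONO * n_disulfides
    avg -= DISULFIDE_AVG * n_disulfides
    if amidated:
        mono -= AMIDATION_MONO
        avg -= AMIDATION_AVG
    return PeptideMass(
        monoisotopic_da=mono,
        average_da=avg,
        n_disulfides=n_disulfides,
        amidated=amidated,
    )
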