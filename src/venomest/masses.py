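"""MALDI peptide-mass census: window filter, species dedup, prediction match.

Peak lists are plain delimited text with a fraction id and an m/z column.
Masses inside the analysis window (default 1-10 kDa, below which matrix
peaks dominate and above which proteins rather than peptides elute) are
deduplicated across fractions into distinct molecular species by a greedy
tolerance merge, giving the peptide-diversity census; species can then be
matched against predicted mature-peptide masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._tables import PROTON
from .precursor import PeptideMass


@dataclass(frozen=True)
class MassPeak:
    fraction_id: str
    mz: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass(frozen=True)
class Species:
    representative_da: float
    peaks: tuple[MassPeak, ...]


@dataclass(frozen=True)
class SpeciesSet:
    species: tuple[Species, ...]
    tolerance_da: float

    @property
    def count(self) -> int:
        return len(self.species)


def read_peak_list(path: str | Path, fraction_id: str | None = None) -> list[MassPeak]:
    """Read a CSV/TSV peak list: columns (fraction_id, mz) or a single mz
    column when ``fraction_id`` is given."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "mz" not in cols:
        raise ValueError(f"no 'mz' column in {path}")
    if "fraction_id" in cols:
        fractions = df[cols["fraction_id"]].astype(str)
    elif fraction_id is not None:
        fractions = pd.Series([fraction_id] * len(df))
    else:
        raise ValueError("peak list lacks a fraction_id column")
    return [
        MassPeak(fraction_id=f, mz=float(m))
        for f, m in zip(fractions, df[cols["mz"]])
    ]


def window_filter(
    peaks: Iterable[MassPeak], lo: float = 1000.0, hi: float = 10000.0
) -> list[MassPeak]:
    """Keep peaks with lo <= m/z <= hi (idempotent)."""
    return [p for p in peaks if lo <= p.mz <= hi]


def dedup_species(
    peaks: Sequence[MassPeak], tolerance_da: float = 0.5
) -> SpeciesSet:
    """Merge peaks across fractions into distinct molecular species.

    Peaks are sorted by m/z and greedily merged: a peak joins the current
    species while it lies within ``tolerance_da`` of the species' running
    mean, otherwise it starts a new species. Sorting first makes the count
    invariant under input permutation.
    """
    if tolerance_da < 0:
        raise ValueError("tolerance must be >= 0")
    ordered = sorted(peaks, key=lambda p: (p.mz, p.fraction_id))
    groups: list[list[MassPeak]] = []
    mean = None
    for p in ordered:
        if mean is not None and abs(p.mz - mean) <= tolerance_da:
            groups[-1].append(p)
            mean = sum(q.mz for q in groups[-1]) / len(groups[-1])
        else:
            groups.append([p])
            mean = p.mz
    species = tuple(
        Species(
            representative_da=sum(q.mz for q in g) / len(g),
            peaks=tuple(g),
        )
        for g in groups
    )
    return SpeciesSet(species=species, tolerance_da=tolerance_da)


def match_predictions(
    species_set: SpeciesSet,
    predicted: Sequence[tuple[str, PeptideMass]],
    tolerance_da: float = 0.5,
    assume_protonated: bool = False,
) -> pd.DataFrame:
    """Match each observed species to predicted mature-peptide masses.

    Both the monoisotopic and the average predicted mass are tried; when
    ``assume_protonated`` the observed representative is first reduced by
    one proton mass. Unmatched species get an empty match list.
    """
    rows = []
    for sp in species_set.species:
        neutral = sp.representative_da - (PROTON if assume_protonated else 0.0)
        matches = []
        for name, pm in predicted:
            err_mono = abs(neutral - pm.monoisotopic_da)
            err_avg = abs(neutral - pm.average_da)
            if min(err_mono, err_avg) <= tolerance_da:
                matches.append((name, min(err_mono, err_avg)))
        matches.sort(key=lambda t: t[1])
        rows.append(
            dict(
                representative_da=sp.representative_da,
                n_peaks=len(sp.peaks),
                n_matches=len(matches),
                best_match=matches[0][0] if matches else "",
                best_error_da=matches[0][1] if matches else float("nan"),
            )
        )
    return pd.DataFrame(rows)
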