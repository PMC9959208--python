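"""Synthetic venom-gland EST library generator with ground truth.

Emulates a venom-gland cDNA library: a heavy-tailed (zipf-like) per-gene
copy-number law dominated by toxin transcripts, toxin precursors built from
the bundled family templates (signal peptide, optional PQM-terminated
propeptide, cysteine-framework mature peptide, optional -G/-GK/-GGK
amidation signal), housekeeping-like cellular cDNAs, and unannotatable
random cDNAs. Per-copy sequencing noise is uniform base substitution plus
5'-truncation; every emitted EST carries a ground-truth row so downstream
recovery can be scored exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd

from ._tables import SYNONYMOUS
from .catalog import (
    DEFAULT_FAMILY_COUNTS,
    FAMILIES,
    FamilyTemplate,
    cellular_panel,
    family_templates,
)
from .precursor import apply_amidation
from .qc import LIBRARY, ESTRecord

#: substitution alphabet for toxin-template diversification: no new
#: cysteines (framework-preserving) and no new arginines (PQM-preserving)
_TOXIN_MUT_ALPHABET = "ADEFGHIKLMNPQSTVWY"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


def _default_family_weights() -> dict[str, float]:
    total = sum(DEFAULT_FAMILY_COUNTS.values())
    return {f: DEFAULT_FAMILY_COUNTS[f] / total for f in FAMILIES}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic library.

    Copy numbers follow ``rank ** -copy_law`` within each category,
    apportioned to the per-category EST totals; toxin transcripts dominate
    the library the way venom-gland cDNA libraries are dominated by toxin
    mRNAs.
    """

    n_toxin_genes: int = 60
    n_cellular_genes: int = 100
    n_random_genes: int = 40
    n_toxin_ests: int = 1020
    n_cellular_ests: int = 650
    n_random_ests: int = 330
    family_weights: dict[str, float] = field(default_factory=_default_family_weights)
    copy_law: float = 1.3
    template_mut_rate: float = 0.12
    sub_rate: float = 0.005
    trunc_prob: float = 0.08
    trunc_extent: tuple[float, float] = (0.1, 0.4)
    polya_len: tuple[int, int] = (15, 40)
    utr_len: tuple[int, int] = (180, 320)
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.family_weights.values()) - 1.0) > 1e-9:
            raise ValueError("family_weights must sum to 1")
        for name in ("template_mut_rate", "sub_rate", "trunc_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for name in (
            "n_toxin_genes", "n_cellular_genes", "n_random_genes",
            "n_toxin_ests", "n_cellular_ests", "n_random_ests",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.family_weights) - set(FAMILIES):
            raise ValueError("unknown family letters in family_weights")


@dataclass(frozen=True)
class ToxinGene:
    gene_id: str
    family: str
    entry_id: str
    precursor: str
    signal_end: int
    mature_start: int  # equals propeptide end, or signal end without one
    amid_tail: str
    amidated: bool
    mature_processed: str
    framework: str


def make_toxin_precursor(
    family: str,
    rng: random.Random,
    mut_rate: float = 0.12,
    templates: list[FamilyTemplate] | None = None,
) -> ToxinGene:
    """Build one toxin gene's precursor from a family template.

    The signal peptide, the first eight post-signal residues, the
    propeptide's PQM, the mature terminus, and every cysteine are kept
    fixed; other propeptide/mature positions mutate at ``mut_rate`` from a
    cysteine- and arginine-free alphabet, so the framework, the processing
    sites and the amidation signal all stay intact by construction.
    """
    if templates is None:
        templates = family_templates()
    pool = [t for t in templates if t.family == family]
    if not pool:
        raise ValueError(f"unknown family letter: {family!r}")
    tpl = pool[rng.randrange(len(pool))]

    def mutate(seq: str, frozen: set[int]) -> str:
        out = list(seq)
        for i, ch in enumerate(out):
            if i in frozen or ch in "CR":
                continue
            if rng.random() < mut_rate:
                choices = _TOXIN_MUT_ALPHABET.replace(ch, "")
                out[i] = choices[rng.randrange(len(choices))]
        return "".join(out)

    pro = tpl.propeptide
    mat = tpl.mature_core
    if pro:
        frozen_pro = set(range(8)) | set(range(len(pro) - 4, len(pro)))
        pro = mutate(pro, frozen_pro)
        frozen_mat = set(range(len(mat) - 3, len(mat)))
    else:
        # mature follows the signal directly: keep its first 8 residues
        frozen_mat = set(range(8)) | set(range(len(mat) - 3, len(mat)))
    mat = mutate(mat, frozen_mat)

    tail = tpl.amid_tails[rng.randrange(len(tpl.amid_tails))] if tpl.amid_tails else ""
    precursor = tpl.signal + pro + mat + tail
    mature_start = len(tpl.signal) + len(pro)
    mature_processed, amidated = apply_amidation(mat + tail)
    from .framework import extract_framework

    return ToxinGene(
        gene_id="",
        family=family,
        entry_id=tpl.entry_id,
        precursor=precursor,
        signal_end=len(tpl.signal),
        mature_start=mature_start,
        amid_tail=tail,
        amidated=amidated,
        mature_processed=mature_processed,
        framework=extract_framework(mature_processed).notation,
    )


def reverse_translate_and_package(
    precursor: str, rng: random.Random, config: GeneratorConfig
) -> str:
    """cDNA for a precursor: CDS (uniform synonymous codons) + stop + 3'UTR + poly-A."""
    if not precursor:
        raise ValueError("empty precursor")
    codons = []
    for aa in precursor:
        options = SYNONYMOUS[aa]
        codons.append(options[rng.randrange(len(options))])
    stops = SYNONYMOUS["*"]
    codons.append(stops[rng.randrange(len(stops))])
    utr_n = rng.randint(*config.utr_len)
    utr = "".join(_BASES[rng.randrange(4)] for _ in range(utr_n))
    tail = "A" * rng.randint(*config.polya_len)
    return "".join(codons) + utr + tail


def _apportion(targets: int, n: int, exponent: float) -> list[int]:
    """Deterministic monotone split of ``targets`` ESTs over ``n`` gene ranks."""
    if n == 0:
        return []
    weights = [(r + 1) ** -exponent for r in range(n)]
    total_w = sum(weights)
    cum, counts, prev = 0.0, [], 0
    for w in weights:
        cum += w
        q = int(targets * cum / total_w)
        counts.append(max(1, q - prev))
        prev = q
    counts.sort(reverse=True)
    return counts


def _substitute(seq: str, rng: random.Random, rate: float) -> str:
    if rate <= 0.0:
        return seq
    out = list(seq)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            options = _BASES.replace(ch, "") if ch in _BASES else _BASES
            out[i] = options[rng.randrange(len(options))]
    return "".join(out)


def generate_library(
    config: GeneratorConfig,
) -> tuple[list[ESTRecord], pd.DataFrame]:
    """Generate the EST library plus one ground-truth row per EST."""
    config.validate()
    if config.n_toxin_genes + config.n_cellular_genes + config.n_random_genes == 0:
        raise ValueError("empty library")
    rng = random.Random(config.seed)

    genes: list[dict] = []  # gene-level records with their cDNA
    fams = sorted(config.family_weights)
    fam_w = [config.family_weights[f] for f in fams]
    for g in range(config.n_toxin_genes):
        fam = rng.choices(fams, weights=fam_w, k=1)[0]
        tox = make_toxin_precursor(fam, rng, mut_rate=config.template_mut_rate)
        gene_id = f"tox{g:04d}"
        cdna = reverse_translate_and_package(tox.precursor, rng, config)
        genes.append(
            dict(
                gene_id=gene_id, category="toxin-like", cdna=cdna,
                family=tox.family, entry_id=tox.entry_id,
                precursor=tox.precursor, signal_end=tox.signal_end,
                mature_start=tox.mature_start, amid_tail=tox.amid_tail,
                amidated=tox.amidated, mature_processed=tox.mature_processed,
                framework=tox.framework,
            )
        )
    panel = cellular_panel()
    for g in range(config.n_cellular_genes):
        pid, pseq = panel[rng.randrange(len(panel))]
        protein = list(pseq)
        for i in range(1, len(protein)):
            if rng.random() < 0.10:
                options = _AA20.replace(protein[i], "")
                protein[i] = options[rng.randrange(len(options))]
        protein = "".join(protein)
        gene_id = f"cel{g:04d}"
        cdna = reverse_translate_and_package(protein, rng, config)
        genes.append(
            dict(
                gene_id=gene_id, category="cellular", cdna=cdna,
                family="", entry_id=pid, precursor=protein,
                signal_end=-1, mature_start=-1, amid_tail="",
                amidated=False, mature_processed="", framework="",
            )
        )
    if config.n_random_genes:
        from .annotate import NON_MATCHED as _NM, PanelIndex, categorize

        tox_idx = PanelIndex("toxin", [(t.entry_id, t.precursor()) for t in family_templates()])
        cell_idx = PanelIndex("cellular", panel)
    for g in range(config.n_random_genes):
        # rejection-sample so the non-matched class has no homology hit by
        # construction (uniform sequences occasionally brush a panel)
        for _attempt in range(50):
            body_len = rng.randint(380, 700)
            body = "".join(_BASES[rng.randrange(4)] for _ in range(body_len))
            probe = ESTRecord(id="probe", seq=body, origin=LIBRARY)
            call, _orf = categorize(probe, tox_idx, cell_idx)
            if call.category == _NM:
                break
        cdna = body + "A" * rng.randint(*config.polya_len)
        genes.append(
            dict(
                gene_id=f"rnd{g:04d}", category="non-matched", cdna=cdna,
                family="", entry_id="", precursor="",
                signal_end=-1, mature_start=-1, amid_tail="",
                amidated=False, mature_processed="", framework="",
            )
        )

    copy_plan: list[tuple[dict, int]] = []
    for category, target in (
        ("toxin-like", config.n_toxin_ests),
        ("cellular", config.n_cellular_ests),
        ("non-matched", config.n_random_ests),
    ):
        cat_genes = [g for g in genes if g["category"] == category]
        counts = _apportion(target, len(cat_genes), config.copy_law)
        copy_plan.extend(zip(cat_genes, counts))

    records: list[ESTRecord] = []
    truth_rows: list[dict] = []
    for gene, n_copies in copy_plan:
        for c in range(n_copies):
            est_id = f"sim|{gene['gene_id']}|{c:03d}"
            seq = gene["cdna"]
            trunc_nt = 0
            if config.trunc_prob > 0 and rng.random() < config.trunc_prob:
                lo, hi = config.trunc_extent
                trunc_nt = int(len(seq) * rng.uniform(lo, hi))
                seq = seq[trunc_nt:]
            seq = _substitute(seq, rng, config.sub_rate)
            records.append(ESTRecord(id=est_id, seq=seq, origin=LIBRARY))
            truth_rows.append(
                dict(
                    est_id=est_id,
                    gene_id=gene["gene_id"],
                    category=gene["category"],
                    family=gene["family"],
                    entry_id=gene["entry_id"],
                    signal_end=gene["signal_end"],
                    mature_start=gene["mature_start"],
                    mature_end=len(gene["precursor"]),
                    amid_tail=gene["amid_tail"],
                    amidated=gene["amidated"],
                    framework=gene["framework"],
                    mature_processed=gene["mature_processed"],
                    truncated=trunc_nt > 0,
                    trunc_nt=trunc_nt,
                    est_len=len(seq),
                )
            )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate_peak_lists(
    truth: pd.DataFrame,
    seed: int = 0,
    n_fractions: int = 51,
    protonated: bool = False,
) -> pd.DataFrame:
    """Per-fraction MALDI peak lists from the true mature-peptide masses.

    Each distinct mature species (all cysteines disulfide-paired, amidation
    applied) is spotted in one or two HPLC fractions; peaks are the neutral
    monoisotopic masses, or [M+H]+ when ``protonated``.
    """
    from .precursor import peptide_mass

    rng = random.Random(seed)
    toxin = truth[truth["category"] == "toxin-like"]
    species = sorted(set(toxin["mature_processed"]) - {""})
    rows = []
    for i, mat in enumerate(species):
        pm = peptide_mass(
            mat, n_disulfides=mat.count("C") // 2,
            amidated=bool(
                toxin.loc[toxin["mature_processed"] == mat, "amidated"].iloc[0]
            ),
        )
        mz = pm.monoisotopic_da + (1.007276 if protonated else 0.0)
        home = rng.randrange(n_fractions)
        fractions = {home}
        if rng.random() < 0.4:
            fractions.add(min(n_fractions - 1, home + 1))
        for f in sorted(fractions):
            rows.append(dict(fraction_id=f"F{f + 1:02d}", mz=round(mz, 4)))
    return pd.DataFrame(rows)
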