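"""End-to-end pipeline orchestration and summary statistics.

Runs QC -> homology annotation -> per-category clustering -> precursor
processing -> framework/family classification -> peptide-mass census, and
computes the summary numbers a venom-gland EST study reports: category
counts and percentages, clustering proportions, family sizes, abundance
shares, and the distinct-species census. When ground truth from the
synthetic generator is supplied, per-EST recovery rates are scored as well.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._rounding import percentage, round_half_up
from .annotate import CELLULAR, NON_MATCHED, TOXIN, OrfCall, PanelIndex, categorize
from .catalog import FAMILIES, cellular_panel, mature_template_panel, toxin_panel
from .cluster import Cluster, ClusterSummary, greedy_cluster, summarize, tally_genes_proteins
from .framework import assign_scaffold, classify_family, extract_framework
from .masses import MassPeak, dedup_species, match_predictions, window_filter
from .precursor import assign_name, peptide_mass, segment_precursor
from .qc import ESTRecord, qc_filter, trim_polya
from .synthetic import GeneratorConfig, generate_library, simulate_peak_lists


@dataclass(frozen=True)
class CategoryTally:
    n_toxin: int
    n_cellular: int
    n_nonmatched: int
    pct_toxin: float
    pct_cellular: float
    pct_nonmatched: float


def category_percentages(n_toxin: int, n_cellular: int, n_nonmatched: int) -> CategoryTally:
    """Category proportions, half-up at two decimals."""
    total = n_toxin + n_cellular + n_nonmatched
    if total <= 0:
        raise ValueError("empty tally")
    return CategoryTally(
        n_toxin=n_toxin,
        n_cellular=n_cellular,
        n_nonmatched=n_nonmatched,
        pct_toxin=percentage(n_toxin, total),
        pct_cellular=percentage(n_cellular, total),
        pct_nonmatched=percentage(n_nonmatched, total),
    )


def abundance_share(group_size: int, category_size: int) -> float:
    """Share of a category's ESTs carried by one group, half-up 2 dp."""
    if category_size <= 0:
        raise ValueError("category_size must be positive")
    if not 0 <= group_size <= category_size:
        raise ValueError("group_size out of range")
    return percentage(group_size, category_size)


def family_size_table(assignments: Sequence[str]) -> dict[str, int]:
    """Per-family counts over the non-redundant toxins, plus the total."""
    table = {f: 0 for f in FAMILIES}
    for fam in assignments:
        table[fam] = table.get(fam, 0) + 1
    table["total"] = sum(v for k, v in table.items() if k != "total")
    return table


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_len_exclusive: int = 300
    min_identity_pct: float = 40.0
    min_cov_pct: float = 50.0
    cluster_min_overlap: int = 100
    cluster_min_identity_pct: float = 96.0
    family_min_identity_pct: float = 60.0
    mass_window: tuple[float, float] = (1000.0, 10000.0)
    mass_tolerance_da: float = 0.5
    name_prefix: str = "LcTx"


@dataclass
class PipelineResult:
    kept: list[ESTRecord]
    rejections: list
    annotation: pd.DataFrame  # per-EST category/ORF/precursor calls
    clusters: dict[str, list[Cluster]]
    summaries: dict[str, ClusterSummary]
    tally: CategoryTally
    family_table: dict[str, int]
    n_nonredundant_toxins: int
    species_count: int
    species_matched_pct: float
    report: dict


def annotate_records(
    records: Sequence[ESTRecord], config: PipelineConfig
) -> tuple[list[ESTRecord], list, pd.DataFrame, dict[str, OrfCall | None]]:
    """QC, poly-A trimming, categorisation and toxin-precursor calls."""
    kept, rejections = qc_filter(records, min_len_exclusive=config.min_len_exclusive)
    kept = [trim_polya(r) for r in kept]
    tox_panel = PanelIndex("toxin", toxin_panel())
    cell_panel = PanelIndex("cellular", cellular_panel())
    fam_panel = mature_template_panel()
    rows = []
    orf_calls: dict[str, OrfCall | None] = {}
    serial = 0
    for rec in kept:
        call, orf = categorize(
            rec, tox_panel, cell_panel,
            min_identity_pct=config.min_identity_pct,
            min_cov_pct=config.min_cov_pct,
        )
        orf_calls[rec.id] = orf
        row = dict(
            est_id=rec.id,
            origin=rec.origin,
            polya_len=rec.polya_len,
            category=call.category,
            hit_id=call.best_hit.subject_id if call.best_hit else "",
            hit_identity=call.best_hit.identity_pct if call.best_hit else float("nan"),
            name="", family="", motif="", framework="",
            signal_end=-1, mature_start=-1,
            amidated=False, partial=False,
            mature_peptide="", precursor="",
            mono_da=float("nan"), avg_da=float("nan"),
        )
        if call.category == TOXIN and orf is not None:
            serial += 1
            prec = segment_precursor(
                orf.protein,
                origin=rec.origin,
                has_start=orf.has_start,
                has_stop=orf.has_stop,
            )
            fw = extract_framework(prec.mature_peptide) if prec.mature_peptide else None
            scaffold = assign_scaffold(fw) if fw else None
            fam = (
                classify_family(
                    prec.mature_peptide, fw, fam_panel,
                    min_identity_pct=config.family_min_identity_pct,
                )
                if fw
                else None
            )
            row["name"] = assign_name(
                serial,
                partial=prec.partial_n_terminus,
                transcriptomic=rec.origin == "transcriptomic",
                prefix=config.name_prefix,
            )
            row["family"] = fam.family if fam else ""
            row["motif"] = scaffold.motif_name if scaffold else ""
            row["framework"] = fw.notation if fw else ""
            row["signal_end"] = prec.signal[1] if prec.signal else -1
            row["mature_start"] = prec.mature[0]
            row["amidated"] = prec.amidated
            row["partial"] = prec.partial_n_terminus
            row["mature_peptide"] = prec.mature_peptide
            row["precursor"] = prec.full_seq
            if prec.mature_peptide:
                pm = peptide_mass(
                    prec.mature_peptide,
                    n_disulfides=prec.mature_peptide.count("C") // 2,
                    amidated=prec.amidated,
                )
                row["mono_da"] = pm.monoisotopic_da
                row["avg_da"] = pm.average_da
        rows.append(row)
    return kept, rejections, pd.DataFrame(rows), orf_calls


def cluster_categories(
    kept: Sequence[ESTRecord],
    annotation: pd.DataFrame,
    orf_calls: Mapping[str, OrfCall | None],
    config: PipelineConfig,
) -> tuple[dict[str, list[Cluster]], dict[str, ClusterSummary]]:
    by_id = {r.id: r for r in kept}
    clusters: dict[str, list[Cluster]] = {}
    summaries: dict[str, ClusterSummary] = {}
    for category in (TOXIN, CELLULAR, NON_MATCHED):
        ids = annotation.loc[annotation["category"] == category, "est_id"]
        members = [by_id[i] for i in ids]
        if not members:
            continue
        cls = greedy_cluster(
            members,
            min_overlap=config.cluster_min_overlap,
            min_identity_pct=config.cluster_min_identity_pct,
        )
        trimmed = {r.id: r.trimmed_seq for r in members}
        for cl in cls:
            cl.unique_genes, cl.proteins = tally_genes_proteins(cl, orf_calls, trimmed)
        clusters[category] = cls
        summaries[category] = summarize(category, cls)
    return clusters, summaries


def _consensus_family(consensus: str, config: PipelineConfig) -> str:
    """Family of a contig's consensus sequence, or "" when uncallable.

    The consensus is translated and classified the same way a member read
    would be; because majority-vote columns cancel independent read errors,
    the contig-level call is far more robust than any single read's.
    """
    from .annotate import six_frame_orfs

    orfs = six_frame_orfs(consensus)
    if not orfs:
        return ""
    tox_idx = PanelIndex("toxin", toxin_panel())
    best, best_score = None, None
    for orf in orfs:
        hit = tox_idx.best_hit(orf.protein)
        if hit is not None and (best_score is None or hit.score > best_score):
            best, best_score = orf, hit.score
    if best is None:
        return ""
    prec = segment_precursor(
        best.protein, has_start=best.has_start, has_stop=best.has_stop
    )
    if not prec.mature_peptide:
        return ""
    fw = extract_framework(prec.mature_peptide)
    fam = classify_family(
        prec.mature_peptide,
        fw,
        mature_template_panel(),
        min_identity_pct=config.family_min_identity_pct,
    )
    return fam.family if fam.family != "unassigned" else ""


def run_pipeline(
    config: PipelineConfig,
    records: Sequence[ESTRecord] | None = None,
    peaks: Sequence[MassPeak] | None = None,
) -> PipelineResult:
    """Execute the full analysis; simulate the library when none is given."""
    truth = None
    if records is None:
        records, truth = generate_library(config.generator)
    if peaks is None and truth is not None:
        peak_df = simulate_peak_lists(truth, seed=config.generator.seed)
        peaks = [MassPeak(r.fraction_id, r.mz) for r in peak_df.itertuples()]

    kept, rejections, annotation, orf_calls = annotate_records(records, config)
    clusters, summaries = cluster_categories(kept, annotation, orf_calls, config)

    # member ESTs inherit their contig's consensus-level family call: the
    # majority-vote consensus cancels independent per-read substitutions
    inherited: dict[str, str] = {}
    for cl in clusters.get(TOXIN, []):
        if cl.size < 2 or not cl.consensus:
            continue
        fam = _consensus_family(cl.consensus, config)
        if fam:
            for mid in cl.members:
                inherited[mid] = fam
    if inherited:
        annotation["family"] = [
            inherited.get(est_id, fam)
            for est_id, fam in zip(annotation["est_id"], annotation["family"])
        ]

    n_tox = int((annotation["category"] == TOXIN).sum())
    n_cell = int((annotation["category"] == CELLULAR).sum())
    n_non = int((annotation["category"] == NON_MATCHED).sum())
    tally = category_percentages(n_tox, n_cell, n_non)

    toxins = annotation[annotation["category"] == TOXIN]
    distinct = toxins.drop_duplicates("precursor")
    family_table = family_size_table(
        [f for f in distinct["family"] if f]
    )

    species_count = 0
    species_matched_pct = float("nan")
    if peaks:
        in_window = window_filter(peaks, *config.mass_window)
        species_set = dedup_species(in_window, tolerance_da=config.mass_tolerance_da)
        predicted = [
            (row.name_, peptide_mass(row.mature_peptide,
                                     row.mature_peptide.count("C") // 2,
                                     row.amidated))
            for row in distinct.rename(columns={"name": "name_"}).itertuples()
            if row.mature_peptide
        ]
        matches = match_predictions(
            species_set, predicted, tolerance_da=config.mass_tolerance_da
        )
        species_count = species_set.count
        if species_count:
            species_matched_pct = percentage(
                int((matches["n_matches"] > 0).sum()), species_count
            )

    report = dict(
        n_input=len(records),
        n_kept=len(kept),
        n_rejected=len(rejections),
        tally=asdict(tally),
        pct_clustered={
            cat: s.pct_clustered for cat, s in summaries.items()
        },
        n_clusters={cat: s.n_clusters for cat, s in summaries.items()},
        family_table=family_table,
        n_nonredundant_toxins=len(distinct),
        species_count=species_count,
        species_matched_pct=species_matched_pct,
        thresholds=dict(
            min_len_exclusive=config.min_len_exclusive,
            min_identity_pct=config.min_identity_pct,
            min_cov_pct=config.min_cov_pct,
            cluster_min_overlap=config.cluster_min_overlap,
            cluster_min_identity_pct=config.cluster_min_identity_pct,
            family_min_identity_pct=config.family_min_identity_pct,
        ),
    )
    return PipelineResult(
        kept=kept,
        rejections=rejections,
        annotation=annotation,
        clusters=clusters,
        summaries=summaries,
        tally=tally,
        family_table=family_table,
        n_nonredundant_toxins=len(distinct),
        species_count=species_count,
        species_matched_pct=species_matched_pct,
        report=report,
    )


def score_recovery(annotation: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Per-EST recovery of generator ground truth, in percent.

    Category recovery is over all QC-kept ESTs. Family, segmentation,
    framework and amidation recovery are over the full-length
    (non-truncated) truth-toxin ESTs: a 5'-truncated clone physically lacks
    its N-terminal segments, so segment recovery is undefined for it.
    """
    merged = annotation.merge(truth, on="est_id", suffixes=("", "_true"))
    n = len(merged)
    if n == 0:
        raise ValueError("no overlap between annotation and truth")
    out = {
        "n_scored": float(n),
        "category_recovery_pct": percentage(
            int((merged["category"] == merged["category_true"]).sum()), n
        ),
    }
    tox = merged[(merged["category_true"] == TOXIN) & (~merged["truncated"])]
    if len(tox):
        nt = len(tox)
        out["n_toxin_full_length"] = float(nt)
        out["family_recovery_pct"] = percentage(
            int((tox["family"] == tox["family_true"]).sum()), nt
        )
        out["segmentation_recovery_pct"] = percentage(
            int(
                (
                    (tox["signal_end"] == tox["signal_end_true"])
                    & (tox["mature_start"] == tox["mature_start_true"])
                ).sum()
            ),
            nt,
        )
        out["framework_recovery_pct"] = percentage(
            int((tox["framework"] == tox["framework_true"]).sum()), nt
        )
        out["amidation_recovery_pct"] = percentage(
            int((tox["amidated"] == tox["amidated_true"]).sum()), nt
        )
    return out


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the standard output bundle: tables, FASTA consensus, JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    rows = []
    for cat, cls in result.clusters.items():
        for cl in cls:
            for mid in cl.members:
                rows.append(dict(category=cat, cluster_id=cl.cluster_id, est_id=mid))
    pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    with (out / "report.json").open("w") as fh:
        json.dump(result.report, fh, indent=2, default=float)
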