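"""Greedy EST clustering into contigs and singletons.

ESTs within one annotation category are clustered by single-linkage
agglomeration on pairwise local-alignment overlap: two ESTs are linked when
their best local alignment spans at least ``min_overlap`` columns at
``min_identity_pct`` or better. The resulting partition equals the connected
components of the pairwise-similarity graph; a deterministic processing
order (length descending, then id) fixes cluster numbering and consensus
anchoring across runs.

An exact-k-mer prescreen skips alignments that cannot reach the thresholds:
any alignment of L columns with at most m non-matching columns contains an
exact run of at least (L - m) / (m + 1) bases, so sharing no k-mer of that
length rules the pair out.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import biotite.sequence as bseq
import biotite.sequence.align as balign

from ._rounding import percentage
from .annotate import OrfCall
from .qc import ESTRecord

SIZE_BINS = ("1", "2-5", "6-10", "11-15", "16-30", ">30")


def size_bin(n: int) -> str:
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    if n == 1:
        return "1"
    if n <= 5:
        return "2-5"
    if n <= 10:
        return "6-10"
    if n <= 15:
        return "11-15"
    if n <= 30:
        return "16-30"
    return ">30"


@lru_cache(maxsize=1)
def _nuc_matrix() -> balign.SubstitutionMatrix:
    return balign.SubstitutionMatrix.std_nucleotide_matrix()


def pairwise_overlap_identity(a: str, b: str) -> tuple[int, float]:
    """Best local-alignment overlap between two nucleotide sequences.

    Returns ``(overlap_len, identity_pct)`` — the number of aligned columns
    and the percentage of them that match exactly.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    sa = bseq.NucleotideSequence(a, ambiguous=True)
    sb = bseq.NucleotideSequence(b, ambiguous=True)
    aln = balign.align_optimal(
        sa, sb, _nuc_matrix(), gap_penalty=(-10, -2), local=True, max_number=1
    )[0]
    trace = aln.trace
    if len(trace) == 0:
        return 0, 0.0
    matches = sum(
        1 for ai, bi in trace if ai != -1 and bi != -1 and a[ai] == b[bi]
    )
    return len(trace), 100.0 * matches / len(trace)


@dataclass
class Cluster:
    cluster_id: str
    members: list[str]
    consensus: str = ""
    unique_genes: int = 0
    proteins: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def size_bin(self) -> str:
        return size_bin(self.size)


def _kmers(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _safe_k(min_overlap: int, min_identity_pct: float) -> int:
    """Largest prescreen k that cannot produce false negatives."""
    m = int(min_overlap * (1.0 - min_identity_pct / 100.0))
    guaranteed_run = (min_overlap - m) // (m + 1)
    return max(0, min(16, guaranteed_run))


def _min_shared_kmers(min_overlap: int, min_identity_pct: float, k: int) -> int:
    """Lower bound on distinct shared k-mers for any pair passing the
    thresholds: >= min_overlap matched columns split into at most m+1 exact
    runs lose k-1 k-mers per run. Conservative for non-repetitive sequences
    (repeats can only lower the distinct count; see the methods note)."""
    m = int(min_overlap * (1.0 - min_identity_pct / 100.0))
    return max(1, (min_overlap - m) - (m + 1) * (k - 1))


def _linked(a: str, b: str, min_overlap: int, min_identity_pct: float) -> bool:
    overlap, ident = pairwise_overlap_identity(a, b)
    return overlap >= min_overlap and ident >= min_identity_pct


def greedy_cluster(
    ests: Sequence[ESTRecord],
    min_overlap: int = 100,
    min_identity_pct: float = 96.0,
) -> list[Cluster]:
    """Single-linkage agglomeration of ESTs on overlap similarity.

    ESTs are processed longest-first (ties by id). Each EST joins every
    existing cluster containing a linked member; clusters linked through the
    same EST are merged, so the final partition is exactly the connected
    components of the pairwise-similarity graph. Consensus sequences are
    majority-vote columns anchored on each cluster's seed.
    """
    order = sorted(ests, key=lambda r: (-len(r.trimmed_seq), r.id))
    k = _safe_k(min_overlap, min_identity_pct)
    min_shared = _min_shared_kmers(min_overlap, min_identity_pct, k) if k >= 4 else 0
    seqs = {r.id: r.trimmed_seq for r in order}
    kmer_sets = {r.id: _kmers(r.trimmed_seq, k) for r in order} if k >= 4 else {}
    kmer_index: dict[str, set[int]] = defaultdict(set)

    clusters: list[list[str]] = []  # member ids, seed first; None when merged
    for rec in order:
        seq = rec.trimmed_seq
        if not seq:
            clusters.append([rec.id])
            continue
        if k >= 4:
            candidate_ids = set()
            for km in kmer_sets[rec.id]:
                candidate_ids |= kmer_index.get(km, set())
            candidates = sorted(candidate_ids)
        else:
            candidates = list(range(len(clusters)))
        hits = []
        for ci in candidates:
            members = clusters[ci]
            if members is None:
                continue
            for mid in members:
                if not seqs[mid]:
                    continue
                if k >= 4 and len(kmer_sets[rec.id] & kmer_sets[mid]) < min_shared:
                    continue
                if _linked(seq, seqs[mid], min_overlap, min_identity_pct):
                    hits.append(ci)
                    break
        if not hits:
            ci = len(clusters)
            clusters.append([rec.id])
        else:
            ci = hits[0]
            clusters[ci].append(rec.id)
            for other in hits[1:]:
                clusters[ci].extend(clusters[other])
                for km in set().union(
                    *(kmer_sets[m] for m in clusters[other])
                ) if k >= 4 else ():
                    kmer_index[km].discard(other)
                    kmer_index[km].add(ci)
                clusters[other] = None
        if k >= 4:
            for km in kmer_sets[rec.id]:
                kmer_index[km].add(ci)

    out: list[Cluster] = []
    serial = 0
    for members in clusters:
        if members is None:
            continue
        serial += 1
        cl = Cluster(cluster_id=f"CL{serial:04d}", members=list(members))
        cl.consensus = _consensus(members, seqs, min_overlap, min_identity_pct)
        out.append(cl)
    return out


def _consensus(
    members: Sequence[str],
    seqs: Mapping[str, str],
    min_overlap: int,
    min_identity_pct: float,
) -> str:
    """Majority base per column of a seed-anchored alignment.

    The seed is the first (longest) member; every other member is locally
    aligned to it and votes on the seed columns it covers. Ties break
    alphabetically; uncovered columns keep the seed base.
    """
    seed = seqs[members[0]]
    if not seed or len(members) == 1:
        return seed
    votes: list[Counter] = [Counter({base: 1}) for base in seed]
    sa = bseq.NucleotideSequence(seed, ambiguous=True)
    for mid in members[1:]:
        mseq = seqs[mid]
        if not mseq:
            continue
        sb = bseq.NucleotideSequence(mseq, ambiguous=True)
        aln = balign.align_optimal(
            sa, sb, _nuc_matrix(), gap_penalty=(-10, -2), local=True, max_number=1
        )[0]
        for si, mi in aln.trace:
            if si != -1 and mi != -1:
                votes[si][mseq[mi]] += 1
    return "".join(
        min(c.items(), key=lambda kv: (-kv[1], kv[0]))[0] for c in votes
    )


def tally_genes_proteins(
    cluster: Cluster,
    orf_calls: Mapping[str, OrfCall | None],
    trimmed_seqs: Mapping[str, str],
) -> tuple[int, int]:
    """Count distinct coding sequences and distinct translated precursors.

    A "unique gene" is a distinct CDS nucleotide string among members; a
    "protein" is a distinct translated precursor string. Members without an
    ORF contribute to neither tally.
    """
    from .annotate import revcomp

    cds_set: set[str] = set()
    protein_set: set[str] = set()
    for mid in cluster.members:
        orf = orf_calls.get(mid)
        if orf is None:
            continue
        seq = trimmed_seqs[mid]
        strand = seq if orf.frame > 0 else revcomp(seq)
        cds_set.add(strand[orf.cds_start : orf.cds_end])
        protein_set.add(orf.protein)
    return len(cds_set), len(protein_set)


@dataclass
class ClusterSummary:
    category: str
    n_total: int
    n_clusters: int
    n_singletons: int
    n_contigs: int
    pct_clustered: float
    per_bin: dict[str, dict[str, int]] = field(default_factory=dict)


def pct_clustered(n_total: int, n_singletons: int) -> float:
    """Share of ESTs that fell into contigs, half-up at 2 decimals."""
    return percentage(n_total - n_singletons, n_total)


def summarize(category: str, clusters: Sequence[Cluster]) -> ClusterSummary:
    if not clusters:
        raise ValueError("empty category")
    n_total = sum(c.size for c in clusters)
    n_singletons = sum(1 for c in clusters if c.size == 1)
    per_bin: dict[str, dict[str, int]] = {
        b: {"contigs": 0, "ests": 0, "unique_genes": 0, "proteins": 0}
        for b in SIZE_BINS
    }
    for c in clusters:
        row = per_bin[c.size_bin]
        row["contigs"] += 1
        row["ests"] += c.size
        row["unique_genes"] += c.unique_genes
        row["proteins"] += c.proteins
    return ClusterSummary(
        category=category,
        n_total=n_total,
        n_clusters=len(clusters),
        n_singletons=n_singletons,
        n_contigs=len(clusters) - n_singletons,
        pct_clustered=pct_clustered(n_total, n_singletons),
        per_bin=per_bin,
    )
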