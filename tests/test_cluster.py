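"""Greedy clustering: linkage thresholds, partition properties, oracle."""

import random

import pytest

from venomest.annotate import OrfCall
from venomest.cluster import (
    Cluster,
    greedy_cluster,
    pairwise_overlap_identity,
    pct_clustered,
    size_bin,
    summarize,
    tally_genes_proteins,
)
from venomest.qc import ESTRecord


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng, seq, n_subs):
    out = list(seq)
    for i in rng.sample(range(len(seq)), n_subs):
        out[i] = rng.choice("ACGT".replace(out[i], ""))
    return "".join(out)


from _oracles import brute_force_components


class TestPairwiseOverlap:
    def test_identical_sequences(self):
        seq = rand_seq(random.Random(0), 400)
        ov, ident = pairwise_overlap_identity(seq, seq)
        assert ov == 400 and ident == 100.0

    def test_unrelated_sequences_low_identity(self):
        rng = random.Random(1)
        a, b = rand_seq(rng, 300), rand_seq(rng, 300)
        ov, ident = pairwise_overlap_identity(a, b)
        assert ov < 150 or ident < 90.0

    def test_suffix_prefix_overlap(self):
        rng = random.Random(2)
        shared = rand_seq(rng, 200)
        a = rand_seq(rng, 150) + shared
        b = shared + rand_seq(rng, 150)
        ov, ident = pairwise_overlap_identity(a, b)
        assert ov >= 200 and ident >= 99.0


class TestGreedyCluster:
    def make(self, seqs):
        return [ESTRecord(id=f"e{i}", seq=s) for i, s in enumerate(seqs)]

    def test_two_identical_form_one_contig(self):
        seq = rand_seq(random.Random(3), 400)
        clusters = greedy_cluster(self.make([seq, seq]))
        assert len(clusters) == 1 and clusters[0].size == 2
        assert clusters[0].consensus == seq

    def test_disjoint_sequences_stay_singletons(self):
        rng = random.Random(4)
        clusters = greedy_cluster(self.make([rand_seq(rng, 400) for _ in range(3)]))
        assert len(clusters) == 3
        assert all(c.size == 1 for c in clusters)

    def test_seventeen_noisy_copies_bin_16_30(self):
        rng = random.Random(5)
        gene = rand_seq(rng, 500)
        copies = [mutate(rng, gene, 3) for _ in range(17)]
        clusters = greedy_cluster(self.make(copies))
        assert len(clusters) == 1
        assert clusters[0].size == 17
        assert clusters[0].size_bin == "16-30"

    def test_consensus_majority_restores_gene(self):
        rng = random.Random(6)
        gene = rand_seq(rng, 400)
        copies = [gene] + [mutate(rng, gene, 2) for _ in range(6)]
        clusters = greedy_cluster(self.make(copies))
        assert len(clusters) == 1
        assert clusters[0].consensus == gene

    def test_partition_property(self):
        rng = random.Random(7)
        genes = [rand_seq(rng, 450) for _ in range(3)]
        seqs = [mutate(rng, g, rng.randint(0, 4)) for g in genes for _ in range(4)]
        records = self.make(seqs)
        clusters = greedy_cluster(records)
        member_ids = [m for c in clusters for m in c.members]
        assert sorted(member_ids) == sorted(r.id for r in records)

    def test_determinism(self):
        rng = random.Random(8)
        gene = rand_seq(rng, 420)
        records = self.make([mutate(rng, gene, 2) for _ in range(6)])
        a = [(c.cluster_id, tuple(c.members)) for c in greedy_cluster(records)]
        b = [(c.cluster_id, tuple(c.members)) for c in greedy_cluster(records)]
        assert a == b

    def test_threshold_monotonicity(self):
        """Raising the identity threshold can only split, never merge."""
        rng = random.Random(9)
        gene = rand_seq(rng, 400)
        records = self.make(
            [gene] + [mutate(rng, gene, k) for k in (2, 5, 9, 14, 20)]
        )
        loose = greedy_cluster(records, min_identity_pct=90.0)
        strict = greedy_cluster(records, min_identity_pct=98.0)
        loose_map = {m: i for i, c in enumerate(loose) for m in c.members}
        # strict partition refines the loose partition
        for c in strict:
            assert len({loose_map[m] for m in c.members}) == 1

    def test_matches_brute_force_components(self):
        rng = random.Random(10)
        for _ in range(5):
            genes = [rand_seq(rng, rng.randint(250, 400)) for _ in range(3)]
            seqs = []
            for g in genes:
                for _ in range(rng.randint(1, 4)):
                    copy = mutate(rng, g, rng.randint(0, 5))
                    if rng.random() < 0.3:
                        copy = copy[rng.randint(10, 80) :]
                    seqs.append(copy)
            records = self.make(seqs[:12])
            got = {frozenset(c.members) for c in greedy_cluster(records)}
            want = brute_force_components(records, 100, 96.0)
            assert got == want


class TestTallies:
    def orfs_for(self, seqs):
        calls = {}
        for i, s in enumerate(seqs):
            calls[f"e{i}"] = OrfCall(1, 0, len(s) - len(s) % 3, "", True, False)
        return calls

    def test_identical_pair_counts_one_gene_one_protein(self):
        from venomest._tables import SYNONYMOUS

        protein = "MKA" * 30
        cds = "".join(SYNONYMOUS[a][0] for a in protein)
        cluster = Cluster("c1", ["e0", "e1"])
        calls = {
            "e0": OrfCall(1, 0, len(cds), protein, True, False),
            "e1": OrfCall(1, 0, len(cds), protein, True, False),
        }
        seqs = {"e0": cds, "e1": cds}
        assert tally_genes_proteins(cluster, calls, seqs) == (1, 1)

    def test_synonymous_substitution_collapses_at_protein_level(self):
        from venomest._tables import SYNONYMOUS

        protein = "MKA" * 30
        cds1 = "".join(SYNONYMOUS[a][0] for a in protein)
        # other codons for the degenerate residues, same protein
        cds2 = "".join(SYNONYMOUS[a][-1] for a in protein)
        cluster = Cluster("c1", ["e0", "e1"])
        calls = {
            "e0": OrfCall(1, 0, len(cds1), protein, True, False),
            "e1": OrfCall(1, 0, len(cds2), protein, True, False),
        }
        assert tally_genes_proteins(cluster, calls, {"e0": cds1, "e1": cds2}) == (2, 1)

    def test_nonsynonymous_substitution_counts_two_proteins(self):
        from venomest._tables import SYNONYMOUS

        p1 = "MKA" * 30
        p2 = "MRA" + "MKA" * 29
        cds1 = "".join(SYNONYMOUS[a][0] for a in p1)
        cds2 = "".join(SYNONYMOUS[a][0] for a in p2)
        cluster = Cluster("c1", ["e0", "e1"])
        calls = {
            "e0": OrfCall(1, 0, len(cds1), p1, True, False),
            "e1": OrfCall(1, 0, len(cds2), p2, True, False),
        }
        assert tally_genes_proteins(cluster, calls, {"e0": cds1, "e1": cds2}) == (2, 2)


class TestSummaries:
    def test_size_bins(self):
        assert [size_bin(n) for n in (1, 2, 5, 6, 10, 11, 15, 16, 30, 31, 400)] == [
            "1", "2-5", "2-5", "6-10", "6-10", "11-15", "11-15",
            "16-30", "16-30", ">30", ">30",
        ]

    def test_summary_bookkeeping(self):
        clusters = [Cluster("c1", [f"a{i}" for i in range(17)])] + [
            Cluster(f"s{j}", [f"b{j}"]) for j in range(3)
        ]
        s = summarize("toxin-like", clusters)
        assert s.n_total == 20
        assert s.n_clusters == 4 and s.n_singletons == 3 and s.n_contigs == 1
        assert s.per_bin["16-30"]["ests"] == 17
        assert s.pct_clustered == pct_clustered(20, 3) == 85.0

    def test_empty_category_raises(self):
        with pytest.raises(ValueError, match="empty category"):
            summarize("toxin-like", [])
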