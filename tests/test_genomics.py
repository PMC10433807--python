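import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from dyadtrace import (
    GenomeRecord,
    GenomeSet,
    PairwiseMatrix,
    ani_estimate,
    dyad_cherry_fraction,
    is_ultrametric,
    jaccard_gene_distance,
    mutate_genome,
    partition_by_dyad,
    random_genome,
    snp_distance_matrix,
    strain_identity_call,
    upgma,
)


def make_alignment(seqs: dict[str, str], dyads: dict[str, str] | None = None) -> GenomeSet:
    return GenomeSet(
        records={
            gid: GenomeRecord(gid, s, dyad_id=(dyads or {}).get(gid))
            for gid, s in seqs.items()
        },
        aligned=True,
    )


def brute_force_snps(a: str, b: str) -> int:
    """Per-column scan oracle: unambiguous ACGT mismatches only."""
    count = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT" and x != y:
            count += 1
    return count


class TestSnpDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0),
            ("ACGT", "ACGA", 1),
            ("AC-T", "ACGT", 0),   # gap column skipped
            ("ACNT", "ACGT", 0),   # N column skipped
            ("acgt", "AGGT", 1),   # case-insensitive
            ("ACRT", "ACGT", 0),   # ambiguity code skipped
        ],
    )
    def test_column_semantics(self, a, b, expected):
        m = snp_distance_matrix(make_alignment({"x": a, "y": b}))
        assert m.values[0, 1] == expected

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ACGTN-"))
        for _ in range(20):
            length = int(rng.integers(50, 2000))
            a = "".join(rng.choice(alphabet, size=length, p=[0.23] * 4 + [0.04, 0.04]))
            b = "".join(rng.choice(alphabet, size=length, p=[0.23] * 4 + [0.04, 0.04]))
            m = snp_distance_matrix(make_alignment({"a": a, "b": b}))
            assert m.values[0, 1] == brute_force_snps(a, b)

    def test_planted_substitutions_recovered_exactly(self):
        ref = random_genome(10_000, 1)
        mut, _ = mutate_genome(ref, 37, 2)
        m = snp_distance_matrix(make_alignment({"ref": ref, "mut": mut}))
        assert m.values[0, 1] == 37

    def test_unaligned_input_rejected(self):
        gs = GenomeSet(
            records={"a": GenomeRecord("a", "ACGT"), "b": GenomeRecord("b", "ACGT")},
            aligned=False,
        )
        with pytest.raises(ValueError):
            snp_distance_matrix(gs)


class TestAni:
    def test_self_identity(self):
        g = random_genome(20_000, 3)
        ani, related = ani_estimate(g, g)
        assert related and ani == 1.0

    def test_closed_form_at_half_jaccard(self):
        # ANI(J=0.5, k=21) = 1 - ln(3/2)/21
        j, k = 0.5, 21
        assert 1 + np.log(2 * j / (1 + j)) / k == pytest.approx(1 - np.log(1.5) / 21)
        assert 1 + np.log(2 * j / (1 + j)) / k == pytest.approx(0.9807, abs=1e-4)

    def test_mutated_genome_recovers_rate(self):
        ref = random_genome(100_000, 4)
        mut, _ = mutate_genome(ref, 2000, 5)
        ani, _ = ani_estimate(ref, mut)
        assert ani == pytest.approx(0.980, abs=0.005)

    def test_monotone_in_mutation_rate(self):
        ref = random_genome(100_000, 6)
        anis = []
        for i, r in enumerate((0.001, 0.005, 0.01, 0.02, 0.05)):
            mut, _ = mutate_genome(ref, int(r * 100_000), 10 + i)
            anis.append(ani_estimate(ref, mut)[0])
        assert anis == sorted(anis, reverse=True)

    def test_minhash_converges_to_exact(self):
        ref = random_genome(100_000, 8)
        mut, _ = mutate_genome(ref, 1500, 9)
        exact, _ = ani_estimate(ref, mut, mode="exact_sets")
        sketch, _ = ani_estimate(ref, mut, mode="minhash", sketch_size=5000)
        assert abs(exact - sketch) < 0.002

    def test_unrelated_genomes_flagged(self):
        ani, related = ani_estimate("A" * 100, "C" * 100, k=5)
        assert not related and ani == 0.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            ani_estimate("ACGT", "ACGT", k=21)


class TestJaccardGeneDistance:
    def test_hand_cases(self):
        m = pd.DataFrame(
            {
                "g1": [1, 1, 1, 0],
                "g2": [0, 1, 1, 1],   # {b,c,d} vs {a,b,c} -> 2/4 -> 0.5
                "g3": [1, 1, 1, 0],   # identical to g1 -> 0
                "g4": [0, 0, 0, 0],   # empty set
            },
            index=list("abcd"),
        ).astype(bool)
        d = jaccard_gene_distance(m)
        f = d.to_frame()
        assert f.at["g1", "g2"] == pytest.approx(0.5)
        assert f.at["g1", "g3"] == 0.0
        assert f.at["g1", "g4"] == 1.0

    def test_disjoint_sets_at_distance_one(self):
        m = pd.DataFrame({"g1": [1, 1, 0, 0], "g2": [0, 0, 1, 1]}, index=list("abcd")).astype(bool)
        assert jaccard_gene_distance(m).values[0, 1] == 1.0

    def test_two_empty_sets_at_distance_zero(self):
        m = pd.DataFrame({"g1": [0, 0], "g2": [0, 0]}, index=list("ab")).astype(bool)
        assert jaccard_gene_distance(m).values[0, 1] == 0.0


class TestUpgma:
    def test_three_leaf_closed_form(self):
        m = PairwiseMatrix(
            ["A", "B", "C"], np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float),
            "snp_count",
        )
        tree = upgma(m)
        assert tree.newick() == "((A:1,B:1):2,C:3);"

    def test_all_zero_distances_degenerate(self):
        m = PairwiseMatrix(["A", "B", "C"], np.zeros((3, 3)), "snp_count")
        tree = upgma(m)
        assert is_ultrametric(tree)
        assert max(tree.root_to_leaf_depths()) == 0.0

    def test_ultrametric_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(3, 12))
            d = rng.uniform(1, 100, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            m = PairwiseMatrix([f"g{i}" for i in range(n)], d, "snp_count")
            assert is_ultrametric(upgma(m))

    def test_matches_scipy_average_linkage_heights(self):
        """Cophenetic distances from our UPGMA equal scipy's average linkage."""
        rng = np.random.default_rng(13)
        n = 8
        d = rng.uniform(1, 100, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"g{i}" for i in range(n)]
        tree = upgma(PairwiseMatrix(ids, d, "snp_count"))
        expected = cophenet(average(squareform(d)))

        # leaf-pair cophenetic distance = 2 * height of the LCA
        def coph(tree, a, b):
            node = tree
            while True:
                nxt = [c for c in node.children if {a, b} <= set(c.leaf_names())]
                if not nxt:
                    return 2 * node.height
                node = nxt[0]

        got = [coph(tree, ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
        assert np.allclose(got, expected)

    def test_dyad_blocked_matrix_clusters_dyads(self):
        ids = [f"D{d}-{s}" for d in range(6) for s in "MB"]
        dyads = {g: g.split("-")[0] for g in ids}
        n = len(ids)
        d = np.full((n, n), 1000.0)
        for i in range(n):
            d[i, i] = 0
            for j in range(n):
                if i != j and dyads[ids[i]] == dyads[ids[j]]:
                    d[i, j] = 10.0
        tree = upgma(PairwiseMatrix(ids, d, "snp_count", dyads))
        assert dyad_cherry_fraction(tree, dyads) == 1.0

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            upgma(PairwiseMatrix(["A"], np.zeros((1, 1)), "snp_count"))


class TestPartition:
    def make_matrix(self):
        ids = ["d1-M", "d1-B", "d2-M", "d2-B"]
        dyads = {g: g.split("-")[0] for g in ids}
        d = np.full((4, 4), 100.0)
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 5.0
        d[2, 3] = d[3, 2] = 5.0
        return PairwiseMatrix(ids, d, "snp_count", dyads)

    def test_medians(self):
        part = partition_by_dyad(self.make_matrix())
        assert part.median_within == 5.0
        assert part.median_between == 100.0

    def test_pair_count_conserved(self):
        part = partition_by_dyad(self.make_matrix())
        n = 4
        assert len(part.within_values) + len(part.between_values) == n * (n - 1) // 2

    def test_single_genome_dyad_contributes_only_between(self):
        ids = ["d1-M", "d1-B", "d2-M"]
        dyads = {"d1-M": "d1", "d1-B": "d1", "d2-M": "d2"}
        d = np.array([[0, 5, 90], [5, 0, 90], [90, 90, 0]], dtype=float)
        part = partition_by_dyad(PairwiseMatrix(ids, d, "snp_count", dyads), run_test=False)
        assert len(part.within_values) == 1 and len(part.between_values) == 2

    def test_missing_labels_rejected(self):
        m = self.make_matrix()
        m.dyad_ids.pop("d1-M")
        with pytest.raises(ValueError):
            partition_by_dyad(m)


class TestIdentityCalls:
    def make_ani_matrix(self, value):
        ids = ["d1-M", "d1-B"]
        v = np.array([[1.0, value], [value, 1.0]])
        return PairwiseMatrix(ids, v, "ani", {g: "d1" for g in ids})

    def test_near_identical_pair_called_identical(self):
        origins = {"d1-M": "maternal", "d1-B": "infant"}
        calls = strain_identity_call(self.make_ani_matrix(0.99998), origins)
        assert calls == {"d1": "identical"}

    def test_divergent_pair_called_nonidentical(self):
        origins = {"d1-M": "maternal", "d1-B": "infant"}
        calls = strain_identity_call(self.make_ani_matrix(0.982), origins)
        assert calls == {"d1": "nonidentical"}

    def test_boundary_conventions(self):
        origins = {"d1-M": "maternal", "d1-B": "infant"}
        # ANI exactly at threshold -> exclusive (>) -> nonidentical
        assert strain_identity_call(self.make_ani_matrix(0.999), origins)["d1"] == "nonidentical"
        # SNPs exactly at threshold -> inclusive (<=) -> identical
        ids = ["d1-M", "d1-B"]
        m = PairwiseMatrix(ids, np.array([[0.0, 25.0], [25.0, 0.0]]), "snp_count",
                           {g: "d1" for g in ids})
        assert strain_identity_call(m, origins)["d1"] == "identical"

    def test_one_sided_dyad_not_assessable(self):
        origins = {"d1-M": "maternal", "d1-B": "maternal"}
        calls = strain_identity_call(self.make_ani_matrix(0.99998), origins)
        assert calls == {"d1": "not_assessable"}
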