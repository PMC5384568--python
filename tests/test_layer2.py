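"""String-overlap layer: pooling, duplicate/containment removal, unambiguous
merging, overlap graph with transitive reduction, path spelling."""
from __future__ import annotations

import itertools

import pytest
from Bio.Seq import Seq

from twolayer.layer1 import Contig
from twolayer.layer2 import (
    assemble_paths,
    build_overlap_graph,
    find_overlaps,
    fm_merge,
    pool_contigs,
    remove_duplicates,
    second_layer,
)


def bio_rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mk(cid: str, seq: str) -> Contig:
    return Contig(cid, seq)


def oracle_overlaps(contigs, min_overlap):
    """Quadratic all-pairs oriented suffix-prefix scan (longest per pair)."""
    oriented = {}
    for c in contigs:
        oriented[(c.id, 0)] = c.sequence
        oriented[(c.id, 1)] = bio_rc(c.sequence)
    edges = {}
    for a, sa in oriented.items():
        for b, sb in oriented.items():
            if a[0] == b[0]:
                continue
            for ov in range(min(len(sa), len(sb)) - 1, min_overlap - 1, -1):
                if sa[-ov:] == sb[:ov]:
                    edges[(a, b)] = ov
                    break
    return edges


class TestPoolContigs:
    def test_sizes_add_up_and_provenance_preserved(self, rng):
        assemblies = [
            (k, [Contig(f"L1|k{k}|{i}", random_seq(rng, 60), provenance=(1, k, f"k{k}"))
                 for i in range(n)])
            for k, n in [(37, 3), (47, 0), (57, 2)]
        ]
        pooled = pool_contigs(assemblies)
        assert len(pooled) == 5
        assert pooled[0].provenance == (1, 37, "k37")

    def test_id_collision_is_hard_error(self, rng):
        seq = random_seq(rng, 50)
        with pytest.raises(ValueError):
            pool_contigs([(37, [mk("x", seq)]), (47, [mk("x", seq)])])


class TestRemoveDuplicates:
    def test_exact_duplicate_keeps_smallest_id(self, rng):
        seq = random_seq(rng, 80)
        kept = remove_duplicates([mk("b", seq), mk("a", seq)])
        assert [c.id for c in kept] == ["a"]

    def test_substring_contig_removed(self, rng):
        a = random_seq(rng, 200)
        kept = remove_duplicates([mk("a", a), mk("b", a[40:140])])
        assert [c.id for c in kept] == ["a"]

    def test_reverse_complement_substring_removed(self, rng):
        a = random_seq(rng, 200)
        kept = remove_duplicates([mk("a", a), mk("b", bio_rc(a[40:140]))])
        assert [c.id for c in kept] == ["a"]

    def test_matches_bruteforce_containment_oracle(self, rng):
        genome = random_seq(rng, 800)
        contigs = []
        for i in range(25):
            start = int(rng.integers(0, 700))
            length = int(rng.integers(40, 150))
            seq = genome[start:start + length]
            if i % 4 == 0:
                seq = bio_rc(seq)
            contigs.append(mk(f"c{i:02d}", seq))
        kept = {c.id for c in remove_duplicates(contigs)}
        # oracle: contained iff the sequence (either strand) occurs inside a
        # longer-or-equal contig that itself survives earlier in sort order
        order = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
        expected = []
        for c in order:
            inside = any(
                c.sequence in k.sequence or bio_rc(c.sequence) in k.sequence
                for k in expected
            )
            if not inside:
                expected.append(c)
        assert kept == {c.id for c in expected}


class TestFmMerge:
    def test_unique_overlap_pair_merged(self, rng):
        genome = random_seq(rng, 4000)
        merged = fm_merge([mk("a", genome[0:2000]), mk("b", genome[1900:4000])],
                          min_overlap=45)
        assert len(merged) == 1
        assert len(merged[0].sequence) == 2000 + 2100 - 100
        assert merged[0].sequence in (genome, bio_rc(genome))

    def test_ambiguous_end_not_merged(self, rng):
        stem = random_seq(rng, 200)
        b = stem[-100:] + random_seq(rng, 150)
        c = stem[-100:] + random_seq(rng, 150)
        merged = fm_merge([mk("a", stem), mk("b", b), mk("c", c)], min_overlap=45)
        assert len(merged) == 3

    def test_chain_merges_order_independently(self, rng):
        genome = random_seq(rng, 3000)
        pieces = [mk("a", genome[0:1200]), mk("b", genome[1100:2100]),
                  mk("c", genome[2000:3000])]
        expected = None
        for perm in itertools.permutations(pieces):
            merged = fm_merge(list(perm), min_overlap=45)
            seqs = sorted(c.sequence for c in merged)
            if expected is None:
                expected = seqs
            assert seqs == expected
        assert len(expected) == 1 and len(expected[0]) == 3000

    def test_below_threshold_not_merged(self, rng):
        genome = random_seq(rng, 1000)
        merged = fm_merge([mk("a", genome[0:520]), mk("b", genome[480:1000])],
                          min_overlap=45)
        assert len(merged) == 2  # 40 bp overlap stays below the threshold


class TestOverlapGraph:
    def test_overlap_below_threshold_has_no_edge(self, rng):
        genome = random_seq(rng, 500)
        contigs = [mk("a", genome[0:260]), mk("b", genome[216:500])]  # 44 bp
        graph = build_overlap_graph(contigs, min_overlap=45)
        assert graph.edges == []

    def test_detection_matches_bruteforce_scan(self, rng):
        genome = random_seq(rng, 2000)
        contigs = []
        for i in range(20):
            start = int(rng.integers(0, 1500))
            length = int(rng.integers(100, 400))
            seq = genome[start:start + length]
            if i % 3 == 0:
                seq = bio_rc(seq)
            contigs.append(mk(f"c{i:02d}", seq))
        contigs = remove_duplicates(contigs)
        found = find_overlaps(contigs, min_overlap=45)
        expected = {
            pair: ov
            for pair, ov in oracle_overlaps(contigs, 45).items()
            if ov < min(len(next(c.sequence for c in contigs if c.id == pair[0][0])),
                        len(next(c.sequence for c in contigs if c.id == pair[1][0])))
        }
        assert found == expected

    def test_transitive_edge_marked_reducible(self, rng):
        genome = random_seq(rng, 700)
        a, b, c = mk("a", genome[0:300]), mk("b", genome[100:400]), mk("c", genome[250:600])
        graph = build_overlap_graph([a, b, c], min_overlap=45)
        # independent oracle on the toy triple: a->c is implied iff
        # ov_ac == ov_ab + ov_bc - len(b)
        ovs = {(e.a, e.b): e.length for e in graph.edges}
        ov_ab = ovs[(("a", 0), ("b", 0))]
        ov_bc = ovs[(("b", 0), ("c", 0))]
        ov_ac = ovs[(("a", 0), ("c", 0))]
        assert ov_ac == ov_ab + ov_bc - 300
        flags = {(e.a, e.b): e.reducible for e in graph.edges}
        assert flags[(("a", 0), ("c", 0))] is True
        assert flags[(("a", 0), ("b", 0))] is False
        assert flags[(("b", 0), ("c", 0))] is False

    def test_no_overlaps_yields_edgeless_graph(self, rng):
        contigs = [mk(f"c{i}", random_seq(rng, 120)) for i in range(5)]
        graph = build_overlap_graph(contigs, min_overlap=45)
        assert graph.edges == []
        final = assemble_paths(graph, min_final_length=0)
        assert sorted(c.sequence for c in final) == sorted(
            min(c.sequence, bio_rc(c.sequence)) for c in contigs
        )


class TestAssemblePaths:
    def test_linear_chain_spells_single_contig(self, rng):
        genome = random_seq(rng, 1500)
        contigs = [mk("a", genome[0:600]), mk("b", genome[500:1100]),
                   mk("c", genome[1000:1500])]
        graph = build_overlap_graph(contigs, min_overlap=45)
        final = assemble_paths(graph, min_final_length=0)
        assert len(final) == 1
        assert final[0].sequence in (genome, bio_rc(genome))

    def test_final_length_filter_at_threshold(self, rng):
        contigs = [mk("a", random_seq(rng, 999)), mk("b", random_seq(rng, 1000)),
                   mk("c", random_seq(rng, 1001))]
        graph = build_overlap_graph(contigs, min_overlap=45)
        final = assemble_paths(graph, min_final_length=1000)
        assert len(final) == 2
        assert sorted(len(c.sequence) for c in final) == [1000, 1001]

    def test_branch_terminates_paths(self, rng):
        stem = random_seq(rng, 400)
        b = stem[-100:] + random_seq(rng, 300)
        c = stem[-100:] + random_seq(rng, 300)
        graph = build_overlap_graph([mk("a", stem), mk("b", b), mk("c", c)],
                                    min_overlap=45)
        final = assemble_paths(graph, min_final_length=0)
        assert len(final) == 3  # no path walks through the fork

    def test_every_input_contained_before_length_filter(self, rng):
        genome = random_seq(rng, 2500)
        contigs = [mk(f"c{i}", genome[max(0, i * 400 - 80):i * 400 + 400])
                   for i in range(6)]
        graph = build_overlap_graph(contigs, min_overlap=45)
        final = assemble_paths(graph, min_final_length=0)
        for contig in contigs:
            assert any(
                contig.sequence in out.sequence or bio_rc(contig.sequence) in out.sequence
                for out in final
            )


def test_second_layer_output_is_genome_sound(rng):
    """Pooled multi-k contigs from one genome stay genome substrings and the
    longest final contig is at least as long as any input contig."""
    genome = random_seq(rng, 3000)
    def windows(w):
        return [genome[i:i + w] for i in range(0, 3000 - w + 1, 1)]
    from twolayer.layer1 import multi_k_assemble
    assemblies = multi_k_assemble(windows(120), k_list=[37, 97], min_coverage=1)
    final = second_layer(assemblies, min_overlap=45, min_final_length=0)
    assert final
    longest_in = max(len(c.sequence) for _k, cs in assemblies for c in cs)
    assert max(len(c.sequence) for c in final) >= longest_in
    for contig in final:
        assert contig.sequence in genome or bio_rc(contig.sequence) in genome
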