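import numpy as np
import pytest

from ecnet.core_network import CoreNetwork, symmetrize
from ecnet.datatypes import Strand, TranscriptID
from ecnet.differential import (
    S_ONLY,
    SAS_ONLY,
    as_impacted_subgraphs,
    build_change_motif,
    find_as_impacted,
)


def sense(name):
    return TranscriptID(name, Strand.SENSE)


def anti(name):
    return TranscriptID(name, Strand.ANTISENSE)


def network(ids, arcs):
    index = {str(t): i for i, t in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)), dtype=bool)
    for u, v in arcs:
        A[index[str(u)], index[str(v)]] = True
    return CoreNetwork(list(ids), A)


@pytest.fixture
def motif_config():
    """S-net: S1->S2, S1->S4; SAS-net: S1->AS3 (S1 is AS-impacted)."""
    s_ids = [sense("S1"), sense("S2"), sense("S4")]
    net_S = network(s_ids, [(sense("S1"), sense("S2")),
                            (sense("S1"), sense("S4")),
                            (sense("S2"), sense("S1")),
                            (sense("S4"), sense("S1"))])
    sas_ids = s_ids + [anti("S3")]
    net_SAS = network(
        sas_ids,
        [(sense("S1"), anti("S3")),
         (sense("S2"), sense("S4")),
         (sense("S4"), sense("S2"))],
    )
    return net_S, net_SAS


class TestFindASImpacted:
    def test_motif_configuration(self, motif_config):
        net_S, net_SAS = motif_config
        impacted = find_as_impacted(net_S, net_SAS)
        assert impacted == {sense("S1")}

    def test_identical_networks_empty(self):
        ids = [sense("a"), sense("b")]
        net = network(ids, [(sense("a"), sense("b")), (sense("b"), sense("a"))])
        assert find_as_impacted(net, net) == set()

    def test_empty_sas_neighborhood_not_impacted(self):
        # gene whose SAS row is empty must not count as impacted
        s_ids = [sense("a"), sense("b")]
        net_S = network(s_ids, [(sense("a"), sense("b")),
                                (sense("b"), sense("a"))])
        net_SAS = network(s_ids + [anti("x")], [(sense("b"), sense("a"))])
        assert find_as_impacted(net_S, net_SAS) == set()

    def test_isolated_in_s_not_impacted(self):
        s_ids = [sense("a"), sense("b")]
        net_S = network(s_ids, [(sense("b"), sense("a"))])  # a has no out-edge
        net_SAS = network(s_ids + [anti("a")], [(sense("a"), anti("a")),
                                                (sense("b"), sense("a"))])
        assert find_as_impacted(net_S, net_SAS) == set()

    def test_inconsistent_sense_sets_rejected(self):
        net_S = network([sense("a"), sense("b")], [(sense("a"), sense("b"))])
        net_SAS = network([sense("a"), sense("c")], [(sense("a"), sense("c"))])
        with pytest.raises(ValueError):
            find_as_impacted(net_S, net_SAS)

    def test_planted_injection_recovered(self):
        # end-to-end: anti-sense near-copy steals the target's neighborhood
        from ecnet.core_network import ecn_infer
        from ecnet.mi import copula_transform, mi_matrix, significance_mask
        from ecnet.synthetic import (
            generate_network,
            inject_antisense,
            simulate_expression,
        )

        hits = 0
        for seed in range(5):
            net = generate_network(30, seed=seed)
            X = simulate_expression(net, 50, 0.1, seed=seed)
            target = net.genes[3]
            Xas = inject_antisense(X, [target], 0.95, seed=seed)
            ct_s, ct_sas = copula_transform(X), copula_transform(Xas)
            mi_s = significance_mask(mi_matrix(ct_s), ct_s, 20, 0.05, seed=seed)
            mi_sas = significance_mask(mi_matrix(ct_sas), ct_sas, 20, 0.05, seed=seed)
            impacted = find_as_impacted(ecn_infer(mi_s, 0.05), ecn_infer(mi_sas, 0.05))
            if target in {str(t) for t in impacted}:
                hits += 1
        assert hits >= 4


class TestChangeMotif:
    def test_motif_contents(self, motif_config):
        net_S, net_SAS = motif_config
        motif = build_change_motif(sense("S1"), net_S, net_SAS)
        assert motif.center == sense("S1")
        assert motif.s_neighbors == {sense("S2"), sense("S4")}
        assert motif.sas_neighbors == {anti("S3")}
        labels = {(str(u), str(v)): lab for u, v, lab in motif.edges}
        assert labels[("S1", "S2")] == S_ONLY
        assert labels[("S1", "S4")] == S_ONLY
        assert labels[("S1", "S3_AS")] == SAS_ONLY

    def test_enlarged_adds_as_actor_neighbors(self, motif_config):
        net_S, net_SAS = motif_config
        # give AS3 an extra SAS out-neighbor S7
        sas_ids = list(net_SAS.ids) + [sense("S7")]
        arcs = [(u, v) for u, v in net_SAS.edges()]
        arcs.append((anti("S3"), sense("S7")))
        net_S7 = network(
            [sense("S1"), sense("S2"), sense("S4"), sense("S7")],
            [(sense("S1"), sense("S2")), (sense("S1"), sense("S4")),
             (sense("S2"), sense("S1")), (sense("S4"), sense("S1")),
             (sense("S7"), sense("S2")), (sense("S2"), sense("S7"))],
        )
        net_SAS7 = network(sas_ids, arcs)
        motif = build_change_motif(sense("S1"), net_S7, net_SAS7, enlarge=True)
        assert sense("S7") in motif.enlarged

    def test_non_impacted_center_rejected(self, motif_config):
        net_S, net_SAS = motif_config
        with pytest.raises(ValueError):
            build_change_motif(sense("S2"), net_S, net_SAS)

    def test_motif_count_equals_impacted_count(self, motif_config):
        net_S, net_SAS = motif_config
        impacted = find_as_impacted(net_S, net_SAS)
        motifs = [build_change_motif(g, net_S, net_SAS) for g in impacted]
        assert len(motifs) == len(impacted)


class TestASImpactedSubgraphs:
    def test_path_of_three(self):
        ids = [sense(c) for c in "abcx"]
        net = network(ids, [(sense("a"), sense("b")), (sense("b"), sense("c")),
                            (sense("x"), sense("a"))])
        subs = as_impacted_subgraphs(net, {sense("a"), sense("b"), sense("c")}, 3)
        assert len(subs) == 1
        assert subs[0].members == {sense("a"), sense("b"), sense("c")}

    def test_isolated_impacted_filtered(self):
        ids = [sense(c) for c in "abcd"]
        net = network(ids, [(sense("a"), sense("b")), (sense("c"), sense("d"))])
        subs = as_impacted_subgraphs(net, {sense("a"), sense("c")}, 3)
        assert subs == []

    def test_union_find_oracle(self, rng):
        def union_find_components(nodes, edges):
            parent = {n: n for n in nodes}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v in edges:
                parent[find(u)] = find(v)
            comps = {}
            for n in nodes:
                comps.setdefault(find(n), set()).add(n)
            return {frozenset(c) for c in comps.values()}

        for _ in range(50):
            n = 12
            ids = [sense(f"g{i}") for i in range(n)]
            arcs = []
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.12:
                        arcs.append((ids[i], ids[j]))
            net = network(ids, arcs)
            impacted = {t for t in ids if rng.random() < 0.5}
            subs = as_impacted_subgraphs(net, impacted, 1)
            got = {frozenset(str(m) for m in s.members) for s in subs}

            sym = symmetrize(net, "union")
            names = [str(t) for t in impacted]
            und_edges = [
                (str(u), str(v))
                for u, v in sym.edges()
                if str(u) in names and str(v) in names
            ]
            expected = union_find_components(names, und_edges)
            assert got == expected

    def test_members_and_disjointness(self, rng):
        ids = [sense(f"g{i}") for i in range(10)]
        arcs = [(ids[i], ids[i + 1]) for i in range(9)]
        net = network(ids, arcs)
        impacted = set(ids[:4]) | set(ids[6:9])
        subs = as_impacted_subgraphs(net, impacted, 2)
        seen = set()
        for s in subs:
            assert s.members <= impacted
            assert not (s.members & seen)
            seen |= s.members
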