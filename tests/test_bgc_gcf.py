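"""BGC class filtering, gene-level hits, and GCF network construction."""

import numpy as np
import pytest

import symbionet as sn
from symbionet.synthetic_data import mutate_protein, random_protein


def make_bgc(bgc_id, proteins, source="isolate", origin="o1", classes=None, core=0):
    genes = [
        sn.BgcGene(f"{bgc_id}_g{i}", p, is_core=i < core)
        for i, p in enumerate(proteins)
    ]
    return sn.BgcRecord(
        bgc_id=bgc_id, source=source, origin_id=origin,
        product_classes=classes or {"t1pks"}, genes=genes,
        span_bp=sum(len(p) for p in proteins) * 3,
    )


@pytest.fixture(scope="module")
def rng_mod():
    return np.random.default_rng(401)


class TestClassFilter:
    def _rec(self, classes):
        return make_bgc("x", ["MKVLAATRWQ" * 10], classes=set(classes))

    @pytest.mark.parametrize(
        "classes,kept",
        [
            (["t1pks"], True),
            (["transatpks"], True),
            (["nrps"], True),
            (["siderophore"], True),
            (["terpene"], True),
            (["hserlactone"], True),
            (["thiopeptide"], True),
            (["bacteriocin"], False),
            (["lanthipeptide"], False),
            (["nrps", "t1pks"], True),  # hybrid
            (["bacteriocin", "terpene"], True),  # hybrid with one retained class
        ],
    )
    def test_retained_families(self, classes, kept):
        out = sn.filter_bgc_classes([self._rec(classes)])
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert sn.filter_bgc_classes([]) == []

    def test_order_preserved(self):
        recs = [self._rec(["t1pks"]), self._rec(["nrps"]), self._rec(["terpene"])]
        for i, r in enumerate(recs):
            r.bgc_id = f"b{i}"
        assert [r.bgc_id for r in sn.filter_bgc_classes(recs)] == ["b0", "b1", "b2"]


class TestGeneHits:
    def test_identical_bgcs_all_strict_self_hits(self, prototype_bgc):
        hits = sn.gene_hits(prototype_bgc, prototype_bgc, tier="strict")
        assert len(hits) == prototype_bgc.n_genes
        for h in hits:
            assert h.identity_pct == 100.0
            assert h.query_coverage_pct == 100.0
            assert h.subject_coverage_pct == 100.0

    def test_59pct_identity_in_loose_not_strict(self, rng_mod):
        p = random_protein(100, rng_mod)
        # mismatches spread evenly: max match run of 3, so the best local
        # alignment stays full-length at ~59% identity
        q = list(p)
        mutated = 0
        for i in range(100):
            if i % 5 in (0, 2) and mutated < 41:
                choices = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != q[i]]
                q[i] = choices[0]
                mutated += 1
        # fill the remainder at positions i % 5 == 4
        for i in range(4, 100, 5):
            if mutated >= 41:
                break
            choices = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != q[i]]
            q[i] = choices[0]
            mutated += 1
        a = make_bgc("a", ["".join(q)])
        b = make_bgc("b", [p])
        assert len(sn.gene_hits(a, b, tier="loose")) == 1
        assert len(sn.gene_hits(a, b, tier="strict")) == 0

    def test_family_variant_full_strict_hits(self, prototype_bgc):
        """Generator guarantees >=90% identity, full coverage at d=0.1."""
        [(variant, _)] = sn.make_bgc_family(prototype_bgc, 1, 0.0, 0.10, seed=402)
        hits = sn.gene_hits(variant, prototype_bgc, tier="strict")
        assert len(hits) == variant.n_genes

    def test_best_subject_hit_per_query_gene(self, prototype_bgc):
        hits = sn.gene_hits(prototype_bgc, prototype_bgc, tier="loose")
        assert len(hits) == prototype_bgc.n_genes
        for h in hits:
            # self comparison: each gene's best hit is itself
            assert h.query_gene_id == h.subject_gene_id


class TestDirectionalHit:
    def test_identical_bgcs_score_formula(self, rng_mod):
        prots = [random_protein(120, rng_mod) for _ in range(8)]
        a = make_bgc("a", prots)
        b = make_bgc("b", prots)
        h = sn.directional_hit(a, b)
        assert h.shared_genes == 8
        assert h.synteny_weight == 1.0
        assert h.score == 16.0

    def test_below_min_shared_returns_none(self, rng_mod):
        shared = [random_protein(120, rng_mod) for _ in range(2)]
        a = make_bgc("a", shared + [random_protein(120, rng_mod) for _ in range(2)])
        b = make_bgc("b", shared + [random_protein(120, rng_mod) for _ in range(4)])
        assert sn.directional_hit(a, b, min_shared=3) is None

    def test_reflexive_for_any_bgc_with_enough_genes(self, prototype_bgc):
        h = sn.directional_hit(prototype_bgc, prototype_bgc)
        assert h is not None
        assert h.shared_genes == prototype_bgc.n_genes

    def test_truncated_variant_hits_prototype(self, prototype_bgc):
        fam = sn.make_bgc_family(prototype_bgc, 6, 0.5, 0.0, seed=403)
        for variant, lab in fam:
            if variant.n_genes < 3:
                continue
            h = sn.directional_hit(variant, prototype_bgc)
            assert h is not None
            assert h.shared_genes == variant.n_genes

    def test_scrambled_gene_order_lowers_synteny(self, rng_mod):
        prots = [random_protein(120, rng_mod) for _ in range(6)]
        a = make_bgc("a", prots)
        b = make_bgc("b", prots[::-1])
        h = sn.directional_hit(a, b)
        assert h.shared_genes == 6
        assert h.synteny_weight < 1.0


class TestRefineAndBuild:
    @pytest.mark.parametrize(
        "n,s,expect_edge",
        [(5, 3, True), (5, 2, False), (3, 1, True), (2, 0, False)],
    )
    def test_n_minus_2_truth_table(self, n, s, expect_edge, rng_mod):
        partner_prots = [random_protein(120, rng_mod) for _ in range(8)]
        trunc_prots = partner_prots[:s] + [
            random_protein(120, rng_mod) for _ in range(n - s)
        ]
        partner = make_bgc("partner", partner_prots)
        trunc = make_bgc("trunc", trunc_prots)
        retained, strict = sn.refine_single_directional(trunc, partner)
        assert strict == s
        assert retained is expect_edge
        # through the network builder, with a hand-made single-direction hit
        hit = sn.DirectionalHit("trunc", "partner", n, max(s, 1), 1.0, 2.0 * max(s, 1))
        net = sn.refine_and_build([hit], [trunc, partner])
        assert net.graph.has_edge("trunc", "partner") is expect_edge
        if expect_edge:
            assert net.graph.edges["trunc", "partner"]["edge_type"] == "refined_single"

    def test_bidirectional_edge(self, rng_mod):
        prots = [random_protein(120, rng_mod) for _ in range(5)]
        a, b = make_bgc("a", prots), make_bgc("b", prots)
        hits = sn.all_directional_hits([a, b])
        net = sn.refine_and_build(hits, [a, b])
        assert net.graph.edges["a", "b"]["edge_type"] == "bidirectional"
        assert net.gcf_of["a"] == net.gcf_of["b"]

    def test_planted_families_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        records, labels = [], {}
        for f in range(3):
            proto = sn.make_prototype_bgc(f"proto{f}", 8, seed=500 + f)
            records.append(proto)
            labels[proto.bgc_id] = f"fam{f}"
            for rec, lab in sn.make_bgc_family(
                proto, 4, 0.3, 0.08, seed=600 + f, family_id=f"fam{f}"
            ):
                records.append(rec)
                labels[rec.bgc_id] = lab.family_id
        for s in range(5):
            single = sn.make_prototype_bgc(f"single{s}", 6, seed=700 + s)
            records.append(single)
            labels[single.bgc_id] = f"solo{s}"
        net = sn.refine_and_build(sn.all_directional_hits(records), records)
        ids = [r.bgc_id for r in records]
        ari = adjusted_rand_score([labels[i] for i in ids], [net.gcf_of[i] for i in ids])
        assert ari == 1.0
        assert not any(
            labels[u] != labels[v] for u, v in net.graph.edges
        ), "no inter-family edges expected"

    def test_gcf_partition_and_numbering(self, rng_mod):
        prots = [random_protein(120, rng_mod) for _ in range(5)]
        a, b, c = make_bgc("a", prots), make_bgc("b", prots), make_bgc("zz", [
            random_protein(120, rng_mod) for _ in range(5)
        ])
        net = sn.refine_and_build(sn.all_directional_hits([a, b, c]), [a, b, c])
        # larger component numbered first
        assert net.gcf_of["a"] == net.gcf_of["b"] == "GCF_1"
        assert net.gcf_of["zz"] == "GCF_2"

    def test_edge_set_independent_of_input_order(self, prototype_bgc):
        fam = [r for r, _ in sn.make_bgc_family(prototype_bgc, 3, 0.2, 0.05, seed=800)]
        records = [prototype_bgc] + fam
        n1 = sn.refine_and_build(sn.all_directional_hits(records), records)
        rev = records[::-1]
        n2 = sn.refine_and_build(sn.all_directional_hits(rev), rev)
        assert set(map(frozenset, n1.graph.edges)) == set(map(frozenset, n2.graph.edges))
        assert n1.gcf_of == n2.gcf_of

    def test_network_export(self, tmp_path, prototype_bgc, rng_mod):
        fam = [r for r, _ in sn.make_bgc_family(prototype_bgc, 2, 0.2, 0.05, seed=801)]
        records = [prototype_bgc] + fam + [
            make_bgc("iso", [random_protein(120, rng_mod) for _ in range(4)])
        ]
        net = sn.refine_and_build(sn.all_directional_hits(records), records)
        sn.write_graphml(net, tmp_path / "net.graphml")
        sn.write_sif(net, tmp_path / "net.sif")
        sif = (tmp_path / "net.sif").read_text()
        assert "iso" in sif  # isolated node still listed
        import networkx as nx

        back = nx.read_graphml(tmp_path / "net.graphml")
        assert set(back.nodes) == set(net.graph.nodes)
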