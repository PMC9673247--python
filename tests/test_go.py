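import io
import math

import numpy as np
import pytest

from fruitcore.go import (
    fisher_classic,
    fisher_elim,
    propagate_annotations,
    read_annotations,
    read_obo,
)

MINI_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: branch
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
alt_id: GO:0000033
is_a: GO:0000002 ! branch

[Term]
id: GO:0000004
name: gone
namespace: biological_process
is_obsolete: true
is_a: GO:0000001 ! root process

[Term]
id: GO:0000005
name: attached part
namespace: biological_process
relationship: part_of GO:0000002 ! branch
"""


@pytest.fixture
def dag():
    return read_obo(io.StringIO(MINI_OBO))


class TestReadObo:
    def test_mini_ontology_edges(self, dag):
        assert dag.graph.number_of_nodes() == 4
        assert dag.graph.has_edge("GO:0000002", "GO:0000001")
        assert dag.graph.has_edge("GO:0000003", "GO:0000002")

    def test_obsolete_terms_dropped(self, dag):
        assert "GO:0000004" not in dag
        assert "GO:0000004" in dag.obsolete

    def test_alt_id_resolves_to_canonical(self, dag):
        assert dag.resolve("GO:0000033") == "GO:0000003"
        assert dag.resolve("GO:0000003") == "GO:0000003"
        assert dag.resolve("GO:9999999") is None

    def test_part_of_edge_followed(self, dag):
        assert "GO:0000001" in dag.ancestors("GO:0000005")

    def test_part_of_optional(self):
        nodag = read_obo(io.StringIO(MINI_OBO), include_part_of=False)
        assert nodag.ancestors("GO:0000005") == set()

    def test_cycle_rejected(self):
        cyclic = MINI_OBO + "\n[Term]\nid: GO:0000006\nname: a\nis_a: GO:0000007\n\n[Term]\nid: GO:0000007\nname: b\nis_a: GO:0000006\n"
        with pytest.raises(ValueError, match="cyclic"):
            read_obo(io.StringIO(cyclic))


class TestPropagate:
    def test_leaf_reaches_root(self, dag):
        prop, missing = propagate_annotations({"g1": {"GO:0000003"}}, dag)
        assert prop["g1"] == {"GO:0000003", "GO:0000002", "GO:0000001"}
        assert missing == []

    def test_idempotent(self, dag):
        once, _ = propagate_annotations({"g1": {"GO:0000003"}}, dag)
        twice, _ = propagate_annotations(once, dag)
        assert once == twice

    def test_alt_id_and_unresolved_reporting(self, dag):
        prop, missing = propagate_annotations(
            {"g1": {"GO:0000033", "GO:7777777"}}, dag
        )
        assert "GO:0000003" in prop["g1"]
        assert missing == ["GO:7777777"]

    def test_term_sets_equal_union_over_descendants(self, dag):
        annot = {"g1": {"GO:0000003"}, "g2": {"GO:0000005"}, "g3": {"GO:0000002"}}
        prop, _ = propagate_annotations(annot, dag)
        # brute-force transitive closure per gene
        genes_at = {}
        for g, terms in prop.items():
            for t in terms:
                genes_at.setdefault(t, set()).add(g)
        for term in ("GO:0000001", "GO:0000002"):
            direct = set()
            for g, terms in annot.items():
                for t in terms:
                    if t == term or term in dag.ancestors(t):
                        direct.add(g)
            assert genes_at[term] == direct

    def test_monotone_counts(self, dag):
        annot = {f"g{i}": {"GO:0000003"} for i in range(5)}
        annot["h"] = {"GO:0000002"}
        prop, _ = propagate_annotations(annot, dag)
        genes_at = {}
        for g, terms in prop.items():
            for t in terms:
                genes_at.setdefault(t, set()).add(g)
        assert len(genes_at["GO:0000002"]) >= len(genes_at["GO:0000003"])
        assert len(genes_at["GO:0000001"]) >= len(genes_at["GO:0000002"])


def brute_force_upper_tail(k, N, K, n):
    """P(X >= k) by direct summation of hypergeometric masses."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total


class TestFisherClassic:
    def test_hand_example(self, dag):
        universe = {f"g{i}" for i in range(20)}
        term_genes = {f"g{i}" for i in range(5)}
        study = {"g0", "g1", "g2", "g10", "g11"}
        annot = {g: ({"GO:0000003"} if g in term_genes else set()) for g in universe}
        prop, _ = propagate_annotations(annot, dag)
        res = fisher_classic(study, universe, prop, dag).set_index("term_id")
        assert res.loc["GO:0000003", "p"] == pytest.approx(1126 / 15504, abs=1e-12)

    def test_term_covering_universe_p_one(self, dag):
        universe = {f"g{i}" for i in range(10)}
        annot = {g: {"GO:0000002"} for g in universe}
        prop, _ = propagate_annotations(annot, dag)
        res = fisher_classic(set(list(universe)[:4]), universe, prop, dag)
        assert np.all(res["p"] == 1.0)

    def test_study_outside_universe_rejected(self, dag):
        with pytest.raises(ValueError, match="subset"):
            fisher_classic({"x"}, {"y"}, {}, dag)

    def test_matches_brute_force_tail_sums(self, dag):
        """1,000 random configurations agree with direct tail summation."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            N = int(rng.integers(5, 60))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"g{i}" for i in range(N)}
            term_genes = set(rng.choice(sorted(universe), size=K, replace=False))
            study = set(rng.choice(sorted(universe), size=n, replace=False))
            annot = {g: ({"GO:0000003"} if g in term_genes else set()) for g in universe}
            prop, _ = propagate_annotations(annot, dag)
            res = fisher_classic(study, universe, prop, dag, min_annotated=1)
            got = res.set_index("term_id").loc["GO:0000003", "p"]
            k = len(term_genes & study)
            worst = max(worst, abs(got - brute_force_upper_tail(k, N, K, n)))
        assert worst < 1e-12


class TestFisherElim:
    def make_two_level(self, dag):
        # signal confined to the leaf (GO:0000003); parent inherits its genes
        universe = {f"g{i}" for i in range(40)}
        leaf_genes = {f"g{i}" for i in range(8)}
        mid_genes = {f"g{i}" for i in range(8, 20)}
        annot = {
            g: (
                {"GO:0000003"}
                if g in leaf_genes
                else ({"GO:0000002"} if g in mid_genes else {"GO:0000001"})
            )
            for g in universe
        }
        prop, _ = propagate_annotations(annot, dag)
        study = {f"g{i}" for i in range(8)}  # exactly the leaf genes
        return study, universe, prop

    def test_cutoff_zero_equals_classic(self, dag):
        study, universe, prop = self.make_two_level(dag)
        cla = fisher_classic(study, universe, prop, dag).set_index("term_id")
        eli = fisher_elim(study, universe, prop, dag, elim_cutoff=0.0).set_index(
            "term_id"
        )
        assert (cla["p"] - eli["p"]).abs().max() == 0.0

    def test_parent_decorrelated_child_unchanged(self, dag):
        study, universe, prop = self.make_two_level(dag)
        cla = fisher_classic(study, universe, prop, dag).set_index("term_id")
        eli = fisher_elim(study, universe, prop, dag, elim_cutoff=0.01).set_index(
            "term_id"
        )
        leaf, parent = "GO:0000003", "GO:0000002"
        assert eli.loc[leaf, "p"] == cla.loc[leaf, "p"]
        assert eli.loc[parent, "p"] > cla.loc[parent, "p"]
        # elim never makes any term look more enriched than classic
        joined = cla[["p"]].join(eli[["p"]], rsuffix="_elim")
        assert np.all(joined["p_elim"] >= joined["p"] - 1e-15)

    def test_flat_dag_equals_classic(self):
        flat = read_obo(
            io.StringIO(
                "format-version: 1.2\n\n[Term]\nid: GO:0000008\nname: lone\n"
                "namespace: biological_process\n"
            )
        )
        universe = {f"g{i}" for i in range(10)}
        annot = {g: {"GO:0000008"} for g in list(universe)[:6]}
        prop, _ = propagate_annotations(annot, flat)
        study = set(list(universe)[:3])
        cla = fisher_classic(study, universe, prop, flat)
        eli = fisher_elim(study, universe, prop, flat, elim_cutoff=0.5)
        assert cla["p"].tolist() == eli["p"].tolist()

    def test_order_invariance(self, dag):
        study, universe, prop = self.make_two_level(dag)
        res1 = fisher_elim(study, universe, prop, dag)
        # shuffled copies of the same sets
        res2 = fisher_elim(
            set(sorted(study, reverse=True)),
            set(sorted(universe, reverse=True)),
            dict(reversed(list(prop.items()))),
            dag,
        )
        assert res1.equals(res2)


def test_read_annotations_union_and_parsing(tmp_path):
    f1 = tmp_path / "a.tsv"
    f1.write_text("gene_id\tgo\ng1\tGO:0000001,GO:0000002\ng2\t\n")
    f2 = tmp_path / "b.tsv"
    f2.write_text("gene_id\tgo\ng1\tGO:0000003\n")
    annot = read_annotations([f1, f2])
    assert annot["g1"] == {"GO:0000001", "GO:0000002", "GO:0000003"}
    assert annot["g2"] == set()
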