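import pytest

from ancorder import (
    EvolutionConfig,
    event_ledger,
    infer_pair_ancestor,
    label_internal_nodes,
    order_cousins,
    parse_newick,
    reconstruct_all,
    resolve_copy_number,
    select_sister_pair,
    simulate,
)

from conftest import chloroplast_like, go


class TestResolveCopyNumber:
    @pytest.mark.parametrize(
        "c1,c2,cousins,expected",
        [
            (2, 3, [2], 2),   # YCF1: cousin sides with the two-copy sister
            (4, 6, [6], 6),   # YCF68: cousin confirms six copies
            (2, 0, [6], 2),   # YCF68 presence vote: count from the carrier
            (2, 4, [4], 4),   # ORF56: cousin confirms four copies
            (3, 3, [99], 3),  # agreement returns without consulting cousins
        ],
    )
    def test_voting_rule(self, c1, c2, cousins, expected):
        assert resolve_copy_number(c1, c2, cousins) == expected

    def test_first_agreeing_cousin_wins(self):
        assert resolve_copy_number(2, 5, [7, 5, 2]) == 5

    def test_exhausted_cousins_fall_back_to_min(self):
        assert resolve_copy_number(2, 5, [7, 9]) == 2
        assert resolve_copy_number(2, 5, []) == 2

    def test_presence_vote_requires_first_cousin_presence(self):
        assert resolve_copy_number(2, 0, [0, 6]) == 0  # first cousin lacks it


class TestSisterSelection:
    def test_closest_cherry_wins(self):
        tree = label_internal_nodes(parse_newick("((A,B),(C,D));"))
        states = {
            "A": go("A", ["X", "Y", "Z"]),
            "B": go("B", ["X", "Y", "Z"]),
            "C": go("C", ["X", "Y", "Z"]),
            "D": go("D", ["X", "Q", "R", "S"]),
        }
        c1, c2 = select_sister_pair(tree, states)
        assert sorted((c1.node_id, c2.node_id)) == ["A", "B"]

    def test_tie_breaks_lexicographically(self):
        tree = label_internal_nodes(parse_newick("((C,D),(A,B));"))
        states = {k: go(k, ["X", "Y"]) for k in "ABCD"}
        c1, c2 = select_sister_pair(tree, states)
        assert sorted((c1.node_id, c2.node_id)) == ["A", "B"]

    def test_no_cherry_raises(self):
        tree = label_internal_nodes(parse_newick("((A,B),C);"))
        with pytest.raises(ValueError):
            select_sister_pair(tree, {"A": go("A", ["X"])})


class TestCousinOrdering:
    def test_caterpillar_order(self):
        tree = label_internal_nodes(parse_newick("(((A,B),C),D);"))
        states = {k: go(k, ["X", "Y"]) for k in "ABCD"}
        cherry = tree.find("a")
        assert [n.node_id for n in order_cousins(tree, cherry, states)] == ["C", "D"]

    def test_distance_breaks_topological_ties(self):
        tree = label_internal_nodes(parse_newick("((A,B),(C,D));"))
        states = {
            "A": go("A", ["X", "Y", "Z"]),
            "B": go("B", ["X", "Y", "Z"]),
            "C": go("C", ["P", "Q", "R"]),
            "D": go("D", ["X", "Y", "W"]),
        }
        cherry = tree.find("a")
        assert [n.node_id for n in order_cousins(tree, cherry, states)] == ["D", "C"]

    def test_full_tie_is_lexicographic(self):
        tree = label_internal_nodes(parse_newick("((A,B),(D,C));"))
        states = {k: go(k, ["X", "Y"]) for k in "ABCD"}
        cherry = tree.find("a")
        assert [n.node_id for n in order_cousins(tree, cherry, states)] == ["C", "D"]


class TestInferPairAncestor:
    def test_cousin_supported_gene_enters_ancestor(self, fig_toy):
        state, ev1, ev2 = infer_pair_ancestor(
            fig_toy["AB_D"], fig_toy["ABCDE"], [fig_toy["COUSIN"]], node_label="a"
        )
        assert [o.base_name for o in state.gene_order] == ["A", "B", "C", "D"]
        assert ev1.deletions == [("C", 2)]
        assert ev2.insertions == [("E", 4)]

    def test_identical_sisters_propagate(self):
        g = chloroplast_like("S1", {"YCF68": 2})
        state, ev1, ev2 = infer_pair_ancestor(g, g.rename("S2"), [], node_label="a")
        assert state.gene_order.symbols() == g.symbols()
        assert not ev1.insertions and not ev1.deletions
        assert not ev2.insertions and not ev2.deletions

    def test_unsupported_gene_is_an_insertion(self):
        u1 = go("U1", ["A", "B", "D"])
        u2 = go("U2", ["A", "B", "E", "D"])
        cousin = go("C", ["A", "B", "D"])
        state, _, ev2 = infer_pair_ancestor(u1, u2, [cousin], node_label="a")
        assert [o.base_name for o in state.gene_order] == ["A", "B", "D"]
        assert ("E", 2) in ev2.insertions

    def test_no_cousins_conflict_is_flagged(self):
        u1 = go("U1", ["A", "B"])
        u2 = go("U2", ["A", "C", "B"])
        state, _, ev2 = infer_pair_ancestor(u1, u2, [], node_label="a")
        assert [o.base_name for o in state.gene_order] == ["A", "B"]
        assert state.warnings
        assert ("C", 1) in ev2.insertions

    def test_accounting_identity_holds(self, fig_toy):
        state, ev1, ev2 = infer_pair_ancestor(
            fig_toy["AB_D"], fig_toy["ABCDE"], [fig_toy["COUSIN"]], node_label="a"
        )
        n = len(state.gene_order)
        assert len(fig_toy["AB_D"]) == n + ev1.n_insertions - ev1.n_deletions
        assert len(fig_toy["ABCDE"]) == n + ev2.n_insertions - ev2.n_deletions

    def test_copy_number_case_recorded(self):
        u1 = chloroplast_like("U1", {"YCF68": 6})
        u2 = chloroplast_like("U2", {"YCF68": 4})
        cousin = chloroplast_like("C", {"YCF68": 6})
        state, _, ev2 = infer_pair_ancestor(u1, u2, [cousin], node_label="a")
        assert state.gene_order.copy_count("YCF68") == 6
        assert ("YCF68", 6, 4) in ev2.copy_number_changes


class TestEventLedger:
    def test_equal_orders_empty_ledger(self):
        g = chloroplast_like("P", {"YCF1": 2})
        led = event_ledger(g, g.rename("C"))
        assert not led.insertions and not led.deletions
        assert not led.copy_number_changes

    def test_copy_loss_counted_as_deletions(self):
        parent = chloroplast_like("P", {"YCF68": 6})
        child = chloroplast_like("C", {"YCF68": 4})
        led = event_ledger(parent, child)
        ycf_dels = [d for d in led.deletions if d[0] == "YCF68"]
        assert len(ycf_dels) == 2
        assert led.copy_number_changes == [("YCF68", 6, 4)]

    def test_accounting_identity(self):
        parent = go("P", ["A", "B", "C", "D"])
        child = go("C", ["A", "X", "B", "D", "Y"])
        led = event_ledger(parent, child)
        assert len(child) == len(parent) + led.n_insertions - led.n_deletions


class TestReconstructAll:
    def test_identity_propagation(self):
        tree = parse_newick("((A,B),(C,D));")
        g = chloroplast_like("X", {"YCF68": 2, "YCF1": 2})
        leaves = [g.rename(k) for k in "ABCD"]
        result = reconstruct_all(tree, leaves)
        for state in result.states.values():
            assert state.gene_order.symbols() == g.symbols()
        for led in result.ledgers:
            assert not led.insertions and not led.deletions

    def test_three_leaf_toy(self, fig_toy):
        result = reconstruct_all(
            fig_toy["tree"],
            [fig_toy["AB_D"], fig_toy["ABCDE"], fig_toy["COUSIN"]],
        )
        assert [o.base_name for o in result.states["a"].gene_order] == [
            "A", "B", "C", "D",
        ]
        led = {l.branch: l for l in result.ledgers}
        assert led[("a", "AB_D")].deletions == [("C", 2)]
        assert ("E", 4) in led[("a", "ABCDE")].insertions

    def test_zero_event_simulation_recovered(self):
        tree = label_internal_nodes(parse_newick("((A,B),(C,(D,E)));"))
        config = EvolutionConfig(
            root_length=30, insertion_mean=0, deletion_mean=0,
            duplication_mean=0, inversion_mean=0, seed=3,
        )
        history = simulate(config, tree)
        leaves = [history.true_orders[l.organism_id] for l in tree.leaves()]
        result = reconstruct_all(parse_newick("((A,B),(C,(D,E)));"), leaves)
        for label, state in result.states.items():
            assert state.gene_order.symbols() == history.true_orders[label].symbols()

    def test_missing_leaf_rejected(self):
        with pytest.raises(ValueError, match="no gene order"):
            reconstruct_all(parse_newick("(A,B);"), [go("A", ["X"])])

    def test_non_binary_rejected_unless_resolved(self):
        tree = parse_newick("(A,B,C);")
        leaves = [go(k, ["X", "Y"]) for k in "ABC"]
        with pytest.raises(ValueError, match="binary"):
            reconstruct_all(tree, leaves)
        result = reconstruct_all(parse_newick("(A,B,C);"), leaves,
                                 resolve_polytomies=True)
        assert len(result.states) == 2

    def test_deterministic_byte_identical(self):
        tree_text = "((A,B),(C,(D,E)));"
        config = EvolutionConfig(root_length=25, seed=11, root_duplicates=3)
        history = simulate(config, label_internal_nodes(parse_newick(tree_text)))
        leaves = [history.true_orders[l.organism_id]
                  for l in history.tree.leaves()]
        runs = []
        for _ in range(2):
            res = reconstruct_all(parse_newick(tree_text), leaves)
            from ancorder import write_gene_orders
            runs.append(
                write_gene_orders(
                    [res.states[k].gene_order for k in sorted(res.states)]
                )
                + res.events_table()
                + res.manifest()
            )
        assert runs[0] == runs[1]
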