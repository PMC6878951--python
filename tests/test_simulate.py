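"""Generator tests: species-tree construction, gene-history scenarios with
an independent event-log replay oracle, sequence-evolution calibration,
split-gene and hit-table round trips."""

import numpy as np
import pytest

from lucatrace import (
    DecoySpec,
    ForcedTransfer,
    ScenarioConfig,
    evolve_sequences,
    inject_split_genes,
    is_monophyletic,
    make_hit_table,
    simulate_gene_history,
    simulate_species_tree,
)
from lucatrace.phylo import read_newick, write_newick
from lucatrace.screen import classify_architecture, filter_hits, hits_from_table

from conftest import assert_same_tree, patristic_frame


# ----------------------------------------------------------------------
# species trees
# ----------------------------------------------------------------------

class TestSpeciesTree:
    def test_quartet_stem_is_exact(self):
        sp = simulate_species_tree(2, 2, 5.0, 1.0, seed=3)
        # the two half-stem edges around the root add up to the stem
        root_children = sp.tree.seed_node.child_nodes()
        assert len(root_children) == 2
        assert sum(c.edge.length for c in root_children) == pytest.approx(5.0)
        dists = patristic_frame(sp.tree)
        assert dists[("A1", "B1")] == pytest.approx(5.0 + 2.0)

    def test_stem_edge_bipartitions_match_domains(self):
        sp = simulate_species_tree(8, 8, 0.1, 1.0, seed=5)
        arch = {t for t, d in sp.domain_map.items() if d == "ARCHAEA"}
        assert len(arch) == 8
        assert is_monophyletic(sp.tree, arch)

    def test_deterministic_under_seed(self):
        a = simulate_species_tree(4, 4, 2.0, 1.0, seed=9).to_newick()
        b = simulate_species_tree(4, 4, 2.0, 1.0, seed=9).to_newick()
        assert a == b
        c = simulate_species_tree(4, 4, 2.0, 1.0, seed=10).to_newick()
        assert a != c

    def test_degenerate_crown_rejected(self):
        with pytest.raises(ValueError, match="degenerate crown"):
            simulate_species_tree(1, 4, 1.0, 1.0, seed=0)

    def test_ultrametric_in_time(self):
        sp = simulate_species_tree(5, 7, 2.0, 1.0, seed=11)
        for leaf in sp.tree.leaf_node_iter():
            depth = 0.0
            nd = leaf
            while nd.parent_node is not None:
                depth += nd.parent_node.age - nd.age
                nd = nd.parent_node
            assert depth == pytest.approx(sp.root_age)


# ----------------------------------------------------------------------
# gene histories and the replay oracle
# ----------------------------------------------------------------------

def replay_gene_tree(sp, events):
    """Independent reconstruction of the gene tree from the species tree
    plus the event log alone (valid for non-additive, duplication-free
    histories, where each species edge hosts at most one gene copy).

    Returns a dict of tip-pair patristic distances.
    """
    import dendropy

    root_age = sp.root_age
    hgts = [e for e in events if e.type == "HGT"]
    # events keyed by donor edge and recipient edge, in age order
    by_donor: dict[str, list] = {}
    by_recipient: dict[str, list] = {}
    for e in hgts:
        age = root_age - e.time
        by_donor.setdefault(e.donor, []).append((age, e))
        by_recipient.setdefault(e.recipient, []).append((age, e))
    for d in by_donor.values():
        d.sort(key=lambda p: -p[0])
    for d in by_recipient.values():
        d.sort(key=lambda p: -p[0])

    def label(nd):
        return nd.taxon.label if nd.taxon is not None else nd.label

    def grow(edge_node, age_start):
        """Gene subtree rooted where the copy enters `edge_node`'s edge at
        age_start; returns (node or None, pendant_length)."""
        edge_id = label(edge_node)
        candidates = []
        for age, e in by_donor.get(edge_id, []):
            if age < age_start:
                candidates.append((age, "donate", e))
        for age, e in by_recipient.get(edge_id, []):
            if age < age_start:
                candidates.append((age, "killed", e))
        candidates.sort(key=lambda c: -c[0])
        length = 0.0
        cursor = age_start
        for age, kind, e in candidates:
            if kind == "killed":
                return None, 0.0  # replaced: lineage leaves no descendants
            # donate: fork here
            length += (cursor - age) * edge_node.rate_mult
            by_donor[edge_id].remove((age, e))
            recipient = sp.node_by_edge(e.recipient)
            left, llen = grow(edge_node, age)      # continues on the donor
            right, rlen = grow(recipient, age)     # enters the recipient
            return _join(left, llen, right, rlen, length)
        # no event: run to the bottom of the edge
        length += (cursor - edge_node.age) * edge_node.rate_mult
        if edge_node.is_leaf():
            leaf = dendropy.Node()
            leaf.label = edge_node.taxon.label
            return leaf, length
        kids = edge_node.child_nodes()
        left, llen = grow(kids[0], edge_node.age)
        right, rlen = grow(kids[1], edge_node.age)
        return _join(left, llen, right, rlen, length)

    def _join(left, llen, right, rlen, stem):
        import dendropy

        if left is None and right is None:
            return None, 0.0
        if left is None:
            return right, rlen + stem
        if right is None:
            return left, llen + stem
        node = dendropy.Node()
        node.add_child(left)
        left.edge.length = llen
        node.add_child(right)
        right.edge.length = rlen
        return node, stem

    origin = next(e for e in events if e.type == "ORIGIN")
    if origin.recipient == "ROOT":
        kids = sp.tree.seed_node.child_nodes()
        left, llen = grow(kids[0], root_age)
        right, rlen = grow(kids[1], root_age)
        root, _ = _join(left, llen, right, rlen, 0.0)
    else:
        start = sp.node_by_edge(origin.recipient)
        root, _ = grow(start, root_age - origin.time)

    # patristic distances via recursion (labels are species tips)
    dists = {}

    def collect(nd):
        if not nd.child_nodes():
            return {nd.label: 0.0}
        depths: dict[str, float] = {}
        child_maps = []
        for c in nd.child_nodes():
            sub = collect(c)
            sub = {k: v + c.edge.length for k, v in sub.items()}
            child_maps.append(sub)
            depths.update(sub)
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for a, da in child_maps[i].items():
                    for b, db in child_maps[j].items():
                        dists[tuple(sorted((a, b)))] = da + db
        return depths

    collect(root)
    return dists


class TestGeneHistory:
    def test_vertical_equals_species_tree(self, small_species_tree, vertical_history):
        h = vertical_history
        assert [e.type for e in h.events] == ["ORIGIN"]
        assert_same_tree(h.gene_tree, small_species_tree.tree)

    def test_forced_transfer_into_other_domain_stem(self):
        # gene born on the archaeal half-stem, one transfer into the
        # bacterial half-stem: all bacterial copies form one clade
        sp = simulate_species_tree(6, 6, 3.0, 1.0, seed=21)
        cfg = ScenarioConfig(
            scenario="DOMAIN_ORIGIN_HGT",
            origin_edge="ARCH_CROWN",
            forced_transfers=[
                ForcedTransfer(
                    time=0.5 * (sp.root_age - sp.crown_height),
                    recipient="BACT_CROWN",
                )
            ],
            seed=4,
        )
        h = simulate_gene_history(sp, cfg)
        tips = {l.taxon.label for l in h.gene_tree.leaf_node_iter()}
        bact = {t for t in tips if t.startswith("B")}
        assert bact and bact != tips
        assert is_monophyletic(h.gene_tree, bact)

    @pytest.mark.parametrize("seed", [2, 5, 9, 14])
    def test_replay_oracle_reproduces_gene_tree(self, seed):
        sp = simulate_species_tree(6, 6, 2.0, 1.0, seed=100 + seed)
        cfg = ScenarioConfig(
            scenario="DOMAIN_ORIGIN_HGT",
            origin_edge="BACT_CROWN",
            hgt_rate=0.4,
            forced_transfers=[
                ForcedTransfer(time=sp.root_age - 0.6, donor_domain="BACTERIA",
                               recipient="ARCHAEA"),
            ],
            seed=seed,
        )
        h = simulate_gene_history(sp, cfg)
        replayed = replay_gene_tree(sp, h.events)
        emitted = patristic_frame(h.gene_tree)
        assert set(replayed) == set(emitted)
        for pair in emitted:
            assert replayed[pair] == pytest.approx(emitted[pair], abs=1e-9)

    def test_duplication_creates_paralog_clades(self):
        # search seeds for a history with exactly one duplication and no
        # transfers, then check the two paralog copies bracket the subtree
        sp = simulate_species_tree(5, 5, 1.0, 1.0, seed=42)
        for seed in range(60):
            cfg = ScenarioConfig(
                scenario="VERTICAL_LUCA", duplication_rate=0.08, seed=seed
            )
            h = simulate_gene_history(sp, cfg)
            dups = [e for e in h.events if e.type == "DUPLICATION"]
            if len(dups) != 1:
                continue
            host = dups[0].recipient
            affected = {
                l.taxon.label
                for l in sp.node_by_edge(host).leaf_iter()
            }
            doubled = {t for t, copies in h.copy_map.items() if len(copies) == 2}
            assert doubled == affected
            # each paralog set is a clade in the gene tree
            copies1 = {h.copy_map[t][0] for t in affected}
            copies2 = {h.copy_map[t][1] for t in affected}
            tips = {l.taxon.label for l in h.gene_tree.leaf_node_iter()}
            for cl in (copies1, copies2):
                if cl != tips:
                    assert is_monophyletic(h.gene_tree, cl)
            return
        pytest.fail("no single-duplication history found in seed sweep")

    def test_confined_gene_warns_but_returns(self, caplog):
        sp = simulate_species_tree(4, 4, 1.0, 1.0, seed=8)
        cfg = ScenarioConfig(
            scenario="DOMAIN_ORIGIN_HGT", origin_edge="BACT_CROWN", seed=1
        )
        with caplog.at_level("WARNING"):
            h = simulate_gene_history(sp, cfg)
        assert "confined" in caplog.text
        tips = {l.taxon.label for l in h.gene_tree.leaf_node_iter()}
        assert all(t.startswith("B") for t in tips)

    def test_deterministic_under_seed(self, small_species_tree):
        cfg = ScenarioConfig(
            scenario="DOMAIN_ORIGIN_HGT", origin_edge="BACT_CROWN",
            hgt_rate=0.3, seed=13,
        )
        a = simulate_gene_history(small_species_tree, cfg)
        b = simulate_gene_history(small_species_tree, cfg)
        assert write_newick(a.gene_tree) == write_newick(b.gene_tree)
        assert a.events_frame().equals(b.events_frame())


# ----------------------------------------------------------------------
# sequence evolution
# ----------------------------------------------------------------------

class TestEvolveSequences:
    def test_zero_lengths_give_identical_sequences(self):
        tree = read_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln = evolve_sequences(tree, 50, "WAG", seed=2)
        assert len({aln.sequence(i) for i in aln.ids}) == 1

    def test_poisson_mismatch_matches_closed_form(self):
        t = 0.4
        tree = read_newick(f"(a:{t / 2},b:{t / 2});")
        n = 10_000
        aln = evolve_sequences(tree, n, "POISSON", seed=77)
        p_hat = float((aln.matrix[0] != aln.matrix[1]).mean())
        p_true = (19 / 20) * (1 - np.exp(-20 * t / 19))
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) < 3 * se

    def test_bit_identical_under_seed(self, vertical_history):
        a = evolve_sequences(vertical_history, 120, "WAG", seed=5)
        b = evolve_sequences(vertical_history, 120, "WAG", seed=5)
        assert a.to_fasta_string() == b.to_fasta_string()

    def test_unknown_model_rejected(self, vertical_history):
        with pytest.raises(ValueError, match="unknown substitution model"):
            evolve_sequences(vertical_history, 10, "JTT_TYPO", seed=0)


# ----------------------------------------------------------------------
# split genes & hit tables
# ----------------------------------------------------------------------

class TestSplitAndHits:
    def test_zero_fraction_is_identity(self):
        recs = [("x", "MARNDCEQGH"), ("y", "ILKMFPSTWY")]
        out, manifest = inject_split_genes(recs, 0.0, seed=1)
        assert out == recs and manifest.empty

    def test_fragments_reassemble(self):
        recs = [("x", "MARNDCEQGHILKMFPSTWYV" * 5)]
        out, manifest = inject_split_genes(recs, 1.0, seed=3, overlap=0)
        frags = dict(out)
        row = manifest.iloc[0]
        assert frags[row.fragment_a] + frags[row.fragment_b] == recs[0][1]
        assert len(frags[row.fragment_a]) == row.split_pos

    def test_hit_table_plants_exact_rg_set(self):
        true_ids = [f"RG{i}" for i in range(10)]
        table = make_hit_table(true_ids, DecoySpec(helicase_only=5, topo_only=5), seed=6)
        calls = classify_architecture(hits_from_table(table))
        rg = sorted(c.target_id for c in calls if c.call == "RG")
        assert rg == sorted(true_ids)

    def test_no_true_records_yields_empty_rg_set(self):
        table = make_hit_table([], DecoySpec(helicase_only=4, topo_only=3, weak=2), seed=6)
        kept = filter_hits(hits_from_table(table))
        calls = classify_architecture(kept)
        assert not [c for c in calls if c.call == "RG"]

    def test_hit_table_deterministic(self):
        spec = DecoySpec(helicase_only=2, topo_only=2, weak=1)
        a = make_hit_table(["g1", "g2"], spec, seed=9)
        b = make_hit_table(["g1", "g2"], spec, seed=9)
        assert a.equals(b)
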