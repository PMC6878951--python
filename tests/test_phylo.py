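"""Engine tests: trimming, corrected distances, neighbor joining against
additivity and an external implementation, pruning likelihoods against
closed forms and exhaustive enumeration, branch-length optimisation
against the analytic two-tip MLE."""

import io

import dendropy
import numpy as np
import pandas as pd
import pytest

from lucatrace import Alignment, evolve_sequences
from lucatrace.phylo import (
    LOG_FLOOR,
    SiteLikelihoodMatrix,
    distance_matrix,
    nj_tree,
    optimize_branch_lengths,
    read_newick,
    site_log_likelihoods,
    total_log_likelihood,
    trim_alignment,
    write_newick,
)
from lucatrace.seqmodels import AA_ALPHABET, N_STATES, get_model

from conftest import patristic_frame


def random_alignment(rng, n_rows, n_sites, gap_p=0.0):
    letters = list(AA_ALPHABET)
    rows = []
    for i in range(n_rows):
        chars = rng.choice(letters, size=n_sites)
        if gap_p:
            mask = rng.random(n_sites) < gap_p
            chars = np.where(mask, "-", chars)
        rows.append((f"r{i}", "".join(chars)))
    return Alignment.from_pairs(rows)


def exhaustive_site_loglik(tree, aln, model):
    """Likelihood by explicit summation over the full grid of interior-node
    state assignments (20^k for k interior nodes) — no pruning recursion,
    no contraction ordering; each edge's transition probability is simply
    multiplied onto the joint grid and everything is summed at the end."""
    internal = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    axis = {id(nd): k for k, nd in enumerate(internal)}
    k = len(internal)
    assert k <= 5, "brute-force oracle limited to 20^5 assignments"
    n_sites = aln.n_sites
    out = np.empty(n_sites)

    def along(vec, ax):
        shape = [1] * k
        shape[ax] = N_STATES
        return vec.reshape(shape)

    for s in range(n_sites):
        grid = np.ones((N_STATES,) * k)
        grid *= along(model.pi, axis[id(tree.seed_node)])
        for nd in tree.postorder_node_iter():
            if nd.parent_node is None:
                continue
            p = model.transition_matrix(nd.edge.length or 0.0)
            ax_p = axis[id(nd.parent_node)]
            if nd.is_leaf():
                state = aln.row(nd.taxon.label)[s]
                vec = np.ones(N_STATES) if state < 0 else p[:, state]
                grid = grid * along(vec, ax_p)
            else:
                ax_c = axis[id(nd)]
                shape = [1] * k
                shape[ax_p] = N_STATES
                shape[ax_c] = N_STATES
                # build a (20, 20) slab oriented on (ax_p, ax_c)
                slab = p if ax_p < ax_c else p.T
                grid = grid * slab.reshape(shape)
        lik = grid.sum()
        out[s] = np.log(lik) if lik > 0 else LOG_FLOOR
    return out


class TestTrim:
    def test_gapless_is_identity(self, rng):
        aln = random_alignment(rng, 4, 30)
        trimmed, cols = trim_alignment(aln, 0.5)
        assert trimmed.n_sites == 30 and list(cols) == list(range(30))

    def test_column_above_threshold_dropped(self):
        aln = Alignment.from_pairs(
            [("a", "A-"), ("b", "A-"), ("c", "A-"), ("d", "AC")]
        )
        trimmed, cols = trim_alignment(aln, 0.5)
        assert trimmed.n_sites == 1 and list(cols) == [0]

    def test_threshold_one_keeps_everything(self, rng):
        aln = random_alignment(rng, 4, 25, gap_p=0.4)
        trimmed, _ = trim_alignment(aln, 1.0)
        assert trimmed.n_sites == 25

    def test_all_columns_removed_raises(self):
        aln = Alignment.from_pairs([("a", "--"), ("b", "AC")])
        with pytest.raises(ValueError, match="empty alignment"):
            trim_alignment(aln, 0.2)

    def test_retained_count_monotone_in_threshold(self, rng):
        aln = random_alignment(rng, 6, 40, gap_p=0.3)
        counts = [
            trim_alignment(aln, th)[0].n_sites
            for th in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert counts == sorted(counts)


class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment.from_pairs([("a", "MARND"), ("b", "MARND")])
        d = distance_matrix(aln)
        assert d.loc["a", "b"] == 0.0

    def test_poisson_correction_closed_form(self):
        # 1 mismatch in 10 comparable columns: p = 0.1
        aln = Alignment.from_pairs([("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAC")])
        d = distance_matrix(aln)
        expect = -(19 / 20) * np.log(1 - 2 / 19)
        assert d.loc["a", "b"] == pytest.approx(expect)

    def test_symmetry_and_saturation_cap(self, rng, caplog):
        aln = random_alignment(rng, 5, 40)
        d = distance_matrix(aln, cap=10.0)
        assert np.allclose(d.values, d.values.T)
        # random rows are ~95% different: most pairs saturate at the cap
        off = d.values[np.triu_indices(5, 1)]
        assert (off == 10.0).any()


class TestNeighborJoining:
    def test_additive_distances_recover_tree_exactly(self):
        source = read_newick("((a:1,b:2):1.5,((c:0.5,d:1):2,e:3):0.4,f:2.2);")
        ref = patristic_frame(source)
        labels = sorted({x for pair in ref for x in pair})
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for (x, y), v in ref.items():
            mat.loc[x, y] = mat.loc[y, x] = v
        rebuilt = nj_tree(mat)
        got = patristic_frame(rebuilt)
        for pair, v in ref.items():
            assert got[pair] == pytest.approx(v, abs=1e-10)

    def test_three_taxa_closed_form(self):
        mat = pd.DataFrame(
            [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        tree = nj_tree(mat)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_taxon_order_invariance(self, rng):
        n = 7
        base = rng.uniform(0.2, 2.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        df = pd.DataFrame(d, index=labels, columns=labels)
        perm = rng.permutation(n)
        df2 = df.iloc[perm, perm]
        a = patristic_frame(nj_tree(df))
        b = patristic_frame(nj_tree(df2))
        for pair, v in a.items():
            assert b[pair] == pytest.approx(v, abs=1e-9)

    def test_agrees_with_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        n = 6
        base = rng.uniform(0.5, 2.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        ours = nj_tree(pd.DataFrame(d, index=labels, columns=labels))
        dm = skbio.DistanceMatrix(d, ids=labels)
        theirs_newick = skbio.tree.nj(dm).write(io.StringIO()).getvalue() \
            if hasattr(skbio.tree.nj(dm), "write") else str(skbio.tree.nj(dm))
        theirs = read_newick(str(skbio.tree.nj(dm)))
        # same unrooted topology: compare bipartition sets
        def biparts(t):
            tips = frozenset(l.taxon.label for l in t.leaf_node_iter())
            out = set()
            for nd in t.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                side = frozenset(l.taxon.label for l in nd.leaf_iter())
                if 1 < len(side) < len(tips) - 1:
                    out.add(min(side, tips - side, key=sorted))
            return out
        assert biparts(ours) == biparts(theirs)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)


class TestPruningLikelihood:
    def test_two_tip_invariant_site_closed_form(self):
        model = get_model("POISSON")
        tree = read_newick("(a:0.1,b:0.2);")
        aln = Alignment.from_pairs([("a", "A"), ("b", "A")])
        ll = site_log_likelihoods(tree, aln, model)[0]
        t = 0.3
        expect = (1 / 20) * (1 / 20 + (19 / 20) * np.exp(-20 * t / 19))
        assert ll == pytest.approx(np.log(expect), abs=1e-12)

    def test_zero_length_conflict_hits_floor(self):
        model = get_model("POISSON")
        tree = read_newick("(a:0,b:0);")
        aln = Alignment.from_pairs([("a", "A"), ("b", "R")])
        assert site_log_likelihoods(tree, aln, model)[0] == LOG_FLOOR

    def test_long_branch_reaches_stationarity(self):
        model = get_model("POISSON")
        tree = read_newick("(a:40,b:40);")
        aln = Alignment.from_pairs([("a", "A"), ("b", "R")])
        ll = site_log_likelihoods(tree, aln, model)[0]
        assert ll == pytest.approx(np.log(1 / 400), abs=1e-4)

    @pytest.mark.parametrize("model_name", ["POISSON", "WAG"])
    def test_matches_exhaustive_enumeration(self, model_name, rng):
        model = get_model(model_name)
        for _ in range(5):
            n_tips = int(rng.integers(3, 6))
            sub = rng.uniform(0.05, 1.0, size=(n_tips, n_tips))
            d = (sub + sub.T) / 2
            np.fill_diagonal(d, 0)
            tree = nj_tree(pd.DataFrame(
                d, index=[f"r{i}" for i in range(n_tips)],
                columns=[f"r{i}" for i in range(n_tips)],
            ))
            aln = random_alignment(rng, n_tips, 3, gap_p=0.15)
            got = site_log_likelihoods(tree, aln, model)
            want = exhaustive_site_loglik(tree, aln, model)
            assert np.max(np.abs(got - want)) < 1e-8

    def test_rerooting_invariance(self, rng, vertical_history):
        model = get_model("WAG")
        aln = evolve_sequences(vertical_history, 60, "WAG", seed=3)
        base_tree = vertical_history.gene_tree
        base = total_log_likelihood(base_tree, aln, model)
        edges = [
            i for i, nd in enumerate(base_tree.preorder_node_iter())
            if nd.parent_node is not None and (nd.edge.length or 0) > 0
        ]
        for i in rng.choice(edges, size=5, replace=False):
            t = base_tree.clone(depth=1)
            nd = list(t.preorder_node_iter())[i]
            t.reroot_at_edge(
                nd.edge, length1=nd.edge.length / 2, length2=nd.edge.length / 2
            )
            assert total_log_likelihood(t, aln, model) == pytest.approx(
                base, abs=1e-8
            )

    def test_gamma_mixture_runs_and_totals_match(self, vertical_history):
        model = get_model("WAG", gamma_categories=4, gamma_alpha=0.7)
        aln = evolve_sequences(vertical_history, 40, "WAG", seed=9)
        ll = site_log_likelihoods(vertical_history.gene_tree, aln, model)
        assert np.isfinite(ll).all()
        # mixing over categories must bracket the single-rate value
        single = site_log_likelihoods(
            vertical_history.gene_tree, aln, get_model("WAG")
        )
        assert ll.sum() != pytest.approx(single.sum())


class TestOptimizeBranchLengths:
    def test_two_tip_mle_matches_closed_form(self):
        tree = read_newick("(a:0.05,b:0.05);")
        aln = evolve_sequences(tree, 10_000, "POISSON", seed=12)
        p_hat = float((aln.matrix[0] != aln.matrix[1]).mean())
        mle = -(19 / 20) * np.log(1 - 20 * p_hat / 19)
        opt, _ = optimize_branch_lengths(tree, aln, get_model("POISSON"))
        total = sum(
            nd.edge.length for nd in opt.preorder_node_iter() if nd.parent_node
        )
        assert total == pytest.approx(mle, abs=1e-4)

    def test_loglik_never_decreases_from_truth(self, vertical_history):
        aln = evolve_sequences(vertical_history, 300, "POISSON", seed=4)
        model = get_model("POISSON")
        start = total_log_likelihood(vertical_history.gene_tree, aln, model)
        _, logl = optimize_branch_lengths(
            vertical_history.gene_tree, aln, model, max_sweeps=3
        )
        assert logl >= start - 1e-9

    def test_four_taxon_lengths_recovered(self):
        true = read_newick("((a:0.2,b:0.35):0.25,(c:0.15,d:0.4):0.1);")
        aln = evolve_sequences(true, 5_000, "POISSON", seed=31)
        start = true.clone(depth=1)
        for nd in start.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = 0.3
        opt, _ = optimize_branch_lengths(start, aln, get_model("POISSON"))
        got = patristic_frame(opt)
        want = patristic_frame(true)
        for pair, v in want.items():
            assert abs(got[pair] - v) / v < 0.15


class TestSiteLikelihoodMatrix:
    def test_totals_consistent_and_tsv_round_trip(self, rng):
        values = rng.normal(-3, 0.4, size=(2, 30))
        m = SiteLikelihoodMatrix(["t1", "t2"], values)
        assert np.allclose(m.totals, values.sum(axis=1), atol=1e-9)
        buf = io.StringIO(m.to_tsv_string())
        back = SiteLikelihoodMatrix.from_tsv(buf)
        assert back.tree_ids == ["t1", "t2"]
        assert np.allclose(back.values, values, atol=1e-9)

    def test_newick_round_trip_six_digits(self):
        s = "((a:0.123457,b:1.25):0.5,(c:2,d:3.14159):0.25);"
        tree = read_newick(s)
        assert write_newick(tree).replace(" ", "") == s
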