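"""Minimal phylogenetic engine.

Covers what the origin analysis needs and nothing more: gap-based column
trimming, Poisson-corrected distances, neighbor joining, per-site
log-likelihoods by Felsenstein pruning (with per-node scaling), and
coordinate-wise branch-length optimisation. Trees are ``dendropy.Tree``
objects throughout; Newick round-trips preserve branch lengths to six
significant digits.

The pruning and optimisation code paths share one internal array
representation (:class:`_ArrayTree`); per-edge likelihood curves are
evaluated through the model eigendecomposition, so a branch-length sweep
costs two small matrix products per edge plus a scalar Brent search.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .align import GAP, Alignment
from .seqmodels import N_STATES, SubstitutionModel

logger = logging.getLogger(__name__)

LOG_FLOOR = -700.0  # per-site floor for impossible configurations (t = 0)
MIN_BRANCH = 1e-8
MAX_BRANCH = 25.0
DISTANCE_CAP = 10.0

__all__ = [
    "read_newick",
    "write_newick",
    "trim_alignment",
    "distance_matrix",
    "nj_tree",
    "site_log_likelihoods",
    "total_log_likelihood",
    "optimize_branch_lengths",
    "SiteLikelihoodMatrix",
]


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------

def read_newick(source: str, is_path: bool = False) -> dendropy.Tree:
    """Read a Newick tree; internal labels are kept as support values."""
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if is_path:
        return dendropy.Tree.get(path=source, **kwargs)
    return dendropy.Tree.get(data=source, **kwargs)


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
        unquoted_underscores=True,
    ).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


# ----------------------------------------------------------------------
# Alignment preprocessing
# ----------------------------------------------------------------------

def trim_alignment(aln: Alignment, max_gap_fraction: float) -> tuple[Alignment, np.ndarray]:
    """Drop columns whose gap fraction exceeds the threshold.

    Returns the trimmed alignment and the map from retained columns back
    to original column indices.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    gap_frac = (aln.matrix == GAP).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    if keep.size == 0:
        raise ValueError("empty alignment after trimming")
    return Alignment(aln.ids, aln.matrix[:, keep]), keep


def distance_matrix(
    aln: Alignment,
    correction: str = "POISSON_CORRECTED",
    cap: float = DISTANCE_CAP,
) -> pd.DataFrame:
    """Pairwise distances over comparable (gap-free in both rows) columns.

    ``POISSON_CORRECTED`` applies d = -(19/20) ln(1 - 20p/19); saturated
    pairs (p >= 19/20) and pairs with no comparable columns are set to the
    cap with a warning.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least two sequences")
    m = aln.matrix
    valid = (m != GAP)
    comparable = valid.astype(np.int32) @ valid.astype(np.int32).T
    matches = np.zeros_like(comparable)
    for state in range(N_STATES):
        hit = (m == state).astype(np.int32)
        matches += hit @ hit.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 1.0 - matches / comparable
    no_overlap = comparable == 0
    if no_overlap.any() and no_overlap.sum() > len(aln.ids):
        logger.warning("pairs with no comparable columns set to distance cap")
    p = np.where(no_overlap, 1.0, p)

    key = correction.upper()
    if key == "P_DISTANCE":
        d = p.copy()
    elif key == "POISSON_CORRECTED":
        arg = 1.0 - 20.0 * p / 19.0
        saturated = arg <= np.exp(-cap / (19.0 / 20.0))
        if saturated.any() and not np.all(no_overlap[saturated]):
            logger.warning(
                "%d saturated pairs (p >= ~19/20) capped at distance %.3g",
                int(saturated.sum() // 2), cap,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            d = -(19.0 / 20.0) * np.log(np.where(saturated, 1.0, arg))
        d = np.where(saturated, cap, d)
    else:
        raise ValueError(f"unknown distance correction: {correction!r}")
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return pd.DataFrame(d, index=aln.ids, columns=aln.ids)


# ----------------------------------------------------------------------
# Neighbor joining
# ----------------------------------------------------------------------

def nj_tree(distances: pd.DataFrame | np.ndarray, ids: list[str] | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge (logged). Ties in the Q criterion break on the first
    (row-major) minimum, so the result is deterministic.
    """
    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        d = distances.values.astype(float).copy()
    else:
        d = np.asarray(distances, dtype=float).copy()
        if ids is None:
            ids = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix not symmetric")
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")

    taxon_ns = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes: list[dendropy.Node] = []
    for name in ids:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(name)
        nodes.append(node)

    active = list(range(n))
    clamped = 0
    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj, li, clamped = dij, 0.0, clamped + 1
        if lj < 0:
            li, lj, clamped = dij, 0.0, clamped + 1
        gi, gj = active[i_loc], active[j_loc]
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        nodes[gi].edge.length = li
        parent.add_child(nodes[gj])
        nodes[gj].edge.length = lj
        # new distances
        others = [a for a in active if a not in (gi, gj)]
        new_d = 0.5 * (d[gi, others] + d[gj, others] - dij)
        d[gi, others] = new_d
        d[others, gi] = new_d
        nodes[gi] = parent
        active.remove(gj)

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    seed = tree.seed_node
    for g, length in ((a, la), (b, lb), (c, lc)):
        seed.add_child(nodes[g])
        nodes[g].edge.length = length
    if clamped:
        logger.info("NJ clamped %d negative branch lengths to zero", clamped)
    tree.is_rooted = False
    return tree


# ----------------------------------------------------------------------
# Internal array representation & pruning
# ----------------------------------------------------------------------

@dataclass
class _ArrayTree:
    parent: np.ndarray          # parent index per node (-1 at root)
    lengths: np.ndarray         # edge length above each node (0 at root)
    children: list[list[int]]
    postorder: np.ndarray       # node indices, children before parents
    tip_labels: dict[int, str]  # node index -> taxon label
    nodes: list[dendropy.Node] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "_ArrayTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        tip_labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                if nd.taxon is None:
                    raise ValueError("tip without taxon label")
                tip_labels[i] = nd.taxon.label
        return cls(parent, lengths, children, np.arange(n), tip_labels, nodes)

    def write_lengths_back(self) -> None:
        for i, nd in enumerate(self.nodes):
            if self.parent[i] >= 0:
                nd.edge.length = float(self.lengths[i])


def _tip_partial(row: np.ndarray) -> np.ndarray:
    n_sites = row.size
    part = np.zeros((n_sites, N_STATES))
    gap = row == GAP
    part[gap, :] = 1.0
    idx = np.flatnonzero(~gap)
    part[idx, row[idx]] = 1.0
    return part


def _transition(model: SubstitutionModel, t: float) -> np.ndarray:
    if t <= 0.0:
        return np.eye(N_STATES)
    evals, left, right = model.eigen_system
    p = (left * np.exp(evals * t)) @ right
    np.clip(p, 0.0, None, out=p)
    return p


def _down_partials(
    at: _ArrayTree, aln: Alignment, model: SubstitutionModel, rate: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Post-order conditional likelihoods with per-node log scaling."""
    n_sites = aln.n_sites
    down = np.empty((at.n_nodes, n_sites, N_STATES))
    scale = np.zeros((at.n_nodes, n_sites))
    for i in range(at.n_nodes):
        if at.tip_labels.get(i) is not None:
            if at.tip_labels[i] not in aln:
                raise ValueError(f"tip {at.tip_labels[i]!r} has no sequence")
            down[i] = _tip_partial(aln.row(at.tip_labels[i]))
            continue
        part = np.ones((n_sites, N_STATES))
        sc = np.zeros(n_sites)
        for c in at.children[i]:
            p = _transition(model, at.lengths[c] * rate)
            part = part * (down[c] @ p.T)
            sc += scale[c]
        m = part.max(axis=1)
        nz = m > 0
        part[nz] /= m[nz, None]
        sc = sc + np.where(nz, np.log(np.where(nz, m, 1.0)), 0.0)
        down[i], scale[i] = part, sc
    return down, scale


def _root_site_loglik(
    at: _ArrayTree, down: np.ndarray, scale: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    r = at.root
    lik = down[r] @ pi
    out = np.where(lik > 0, np.log(np.where(lik > 0, lik, 1.0)) + scale[r], LOG_FLOOR)
    return out


def site_log_likelihoods(
    tree: dendropy.Tree, aln: Alignment, model: SubstitutionModel
) -> np.ndarray:
    """Per-site log-likelihoods by pruning; gaps are missing data."""
    at = _ArrayTree.from_dendropy(tree)
    if model.gamma_categories == 1:
        down, scale = _down_partials(at, aln, model)
        return _root_site_loglik(at, down, scale, model.pi)
    per_cat = []
    for rate in model.category_rates:
        down, scale = _down_partials(at, aln, model, rate=rate)
        per_cat.append(_root_site_loglik(at, down, scale, model.pi))
    stacked = np.vstack(per_cat)
    mx = stacked.max(axis=0)
    return mx + np.log(np.exp(stacked - mx).mean(axis=0))


def total_log_likelihood(tree: dendropy.Tree, aln: Alignment, model: SubstitutionModel) -> float:
    return float(site_log_likelihoods(tree, aln, model).sum())


def _outside_partials(
    at: _ArrayTree,
    down: np.ndarray,
    dscale: np.ndarray,
    model: SubstitutionModel,
    rate: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-order 'rest of tree' partials A[c], evaluated at the parent end
    of each node's subtending edge (so site L = (A[c] * pi) @ P(t_c) @ D[c])."""
    n_sites = down.shape[1]
    outside = np.empty_like(down)
    oscale = np.zeros_like(dscale)
    order = at.postorder[::-1]
    root = at.root
    outside[root] = 1.0
    pi = model.pi
    for i in order:
        kids = at.children[i]
        if not kids:
            continue
        if i == root:
            folded = np.ones((n_sites, N_STATES))
            fsc = np.zeros(n_sites)
        else:
            # fold the edge above i into the outside view at node i
            p = _transition(model, at.lengths[i] * rate)
            folded = ((outside[i] * pi[None, :]) @ p) / pi[None, :]
            fsc = oscale[i]
        mats = {c: down[c] @ _transition(model, at.lengths[c] * rate).T for c in kids}
        for c in kids:
            part = folded.copy()
            sc = fsc.copy()
            for s in kids:
                if s == c:
                    continue
                part = part * mats[s]
                sc = sc + dscale[s]
            m = part.max(axis=1)
            nz = m > 0
            part[nz] /= m[nz, None]
            sc = sc + np.where(nz, np.log(np.where(nz, m, 1.0)), 0.0)
            outside[c], oscale[c] = part, sc
    return outside, oscale


def _edge_curve(
    model: SubstitutionModel,
    outside_c: np.ndarray,
    down_c: np.ndarray,
) -> np.ndarray:
    """Coefficients C with per-site logL(t) = log(C @ exp(evals * t))."""
    evals, left, right = model.eigen_system
    w = (outside_c * model.pi[None, :]) @ left
    v = down_c @ right.T
    return w * v


def _curve_loglik(coeffs: np.ndarray, evals: np.ndarray, t: float) -> float:
    lik = coeffs @ np.exp(evals * t)
    lik = np.where(lik > 0, lik, np.exp(LOG_FLOOR))
    return float(np.log(lik).sum())


def optimize_branch_lengths(
    tree: dendropy.Tree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-2,
    max_sweeps: int = 10,
    max_branch: float = MAX_BRANCH,
) -> tuple[dendropy.Tree, float]:
    """Re-estimate branch lengths by coordinate-wise ML.

    Each sweep evaluates inside/outside partials once, then optimises every
    edge against them (a Jacobi-style update); if a simultaneous update
    ever lowers the likelihood the sweep falls back to strictly sequential
    per-edge optimisation, so the total log-likelihood is non-decreasing
    across sweeps. Returns a new tree and its total log-likelihood.
    """
    if model.gamma_categories != 1:
        return _optimize_gamma(tree, aln, model, tol, max_sweeps, max_branch)
    work = tree.clone(depth=1)
    at = _ArrayTree.from_dendropy(work)
    evals = model.eigen_system[0]
    edges = [i for i in range(at.n_nodes) if at.parent[i] >= 0]

    # a two-tip tree has one identifiable parameter: the tip-to-tip path
    # (the split across the root is arbitrary); optimise it directly
    if len(edges) == 2 and all(i in at.tip_labels for i in edges):
        a, b = edges
        pa = _tip_partial(aln.row(at.tip_labels[a]))
        pb = _tip_partial(aln.row(at.tip_labels[b]))
        coeffs = _edge_curve(model, pa, pb)
        res = minimize_scalar(
            lambda t: -_curve_loglik(coeffs, evals, t),
            bounds=(MIN_BRANCH, 2 * max_branch),
            method="bounded",
            options={"xatol": 1e-8},
        )
        at.lengths[a] = at.lengths[b] = float(res.x) / 2.0
        at.write_lengths_back()
        return work, float(-res.fun)

    down, dscale = _down_partials(at, aln, model)
    cur_logl = float(_root_site_loglik(at, down, dscale, model.pi).sum())
    for _sweep in range(max_sweeps):
        outside, _ = _outside_partials(at, down, dscale, model)
        proposal = at.lengths.copy()
        for i in edges:
            coeffs = _edge_curve(model, outside[i], down[i])
            res = minimize_scalar(
                lambda t: -_curve_loglik(coeffs, evals, t),
                bounds=(MIN_BRANCH, max_branch),
                method="bounded",
                options={"xatol": 1e-5},
            )
            proposal[i] = float(res.x)
        old_lengths = at.lengths.copy()
        at.lengths = proposal
        down, dscale = _down_partials(at, aln, model)
        new_logl = float(_root_site_loglik(at, down, dscale, model.pi).sum())
        # damped retreat along the proposal direction if the simultaneous
        # update overshot; full sequential pass only as a last resort
        alpha = 0.5
        while new_logl < cur_logl - 1e-9 and alpha > 0.05:
            at.lengths = old_lengths + alpha * (proposal - old_lengths)
            down, dscale = _down_partials(at, aln, model)
            new_logl = float(_root_site_loglik(at, down, dscale, model.pi).sum())
            alpha /= 2.0
        if new_logl < cur_logl - 1e-9:
            at.lengths = old_lengths
            for i in edges:
                down, dscale = _down_partials(at, aln, model)
                outside, _ = _outside_partials(at, down, dscale, model)
                coeffs = _edge_curve(model, outside[i], down[i])
                res = minimize_scalar(
                    lambda t: -_curve_loglik(coeffs, evals, t),
                    bounds=(MIN_BRANCH, max_branch),
                    method="bounded",
                    options={"xatol": 1e-5},
                )
                if -res.fun >= _curve_loglik(coeffs, evals, at.lengths[i]):
                    at.lengths[i] = float(res.x)
            down, dscale = _down_partials(at, aln, model)
            new_logl = float(_root_site_loglik(at, down, dscale, model.pi).sum())
        improvement = new_logl - cur_logl
        cur_logl = max(new_logl, cur_logl)
        if improvement < tol:
            break
    else:
        logger.warning("branch-length optimisation: max sweeps reached")
    at.write_lengths_back()
    return work, cur_logl


def _optimize_gamma(tree, aln, model, tol, max_sweeps, max_branch):
    """Generic (slower) optimisation for gamma-mixture models."""
    work = tree.clone(depth=1)
    at = _ArrayTree.from_dendropy(work)
    evals = model.eigen_system[0]
    edges = [i for i in range(at.n_nodes) if at.parent[i] >= 0]
    rates = model.category_rates

    def full_logl() -> float:
        at.write_lengths_back()
        return float(site_log_likelihoods(work, aln, model).sum())

    cur = full_logl()
    for _sweep in range(max_sweeps):
        for i in edges:
            curves = []
            for rate in rates:
                down, dscale = _down_partials(at, aln, model, rate=rate)
                outside, oscale = _outside_partials(at, down, dscale, model, rate=rate)
                curves.append((
                    _edge_curve(model, outside[i], down[i]),
                    dscale[i] + oscale[i],
                    rate,
                ))

            def neg(t: float) -> float:
                per_cat = []
                for coeffs, sc, rate in curves:
                    lik = coeffs @ np.exp(evals * (t * rate))
                    lik = np.where(lik > 0, lik, np.exp(LOG_FLOOR))
                    per_cat.append(np.log(lik) + sc)
                stacked = np.vstack(per_cat)
                mx = stacked.max(axis=0)
                return -float((mx + np.log(np.exp(stacked - mx).mean(axis=0))).sum())

            res = minimize_scalar(neg, bounds=(MIN_BRANCH, max_branch),
                                  method="bounded", options={"xatol": 1e-5})
            if -res.fun >= -neg(at.lengths[i]):
                at.lengths[i] = float(res.x)
        new = full_logl()
        if new - cur < tol:
            cur = max(cur, new)
            break
        cur = new
    at.write_lengths_back()
    return work, cur


# ----------------------------------------------------------------------
# Site log-likelihood matrix (feeds the topology tests)
# ----------------------------------------------------------------------

class SiteLikelihoodMatrix:
    """Per-tree x per-site log-likelihoods.

    The RELL resampling machinery works on this matrix alone; no
    likelihood is ever recomputed during a topology test.
    """

    def __init__(self, tree_ids: list[str], values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(tree_ids):
            raise ValueError("values must be (n_trees, n_sites)")
        if len(set(tree_ids)) != len(tree_ids):
            raise ValueError("duplicate tree ids")
        self.tree_ids = list(tree_ids)
        self.values = values

    @classmethod
    def from_trees(
        cls,
        trees: dict[str, dendropy.Tree],
        aln: Alignment,
        model: SubstitutionModel,
    ) -> "SiteLikelihoodMatrix":
        ids, rows = [], []
        for name, tree in trees.items():
            ids.append(name)
            rows.append(site_log_likelihoods(tree, aln, model))
        return cls(ids, np.vstack(rows))

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_tsv(self, path_or_handle) -> None:
        df = pd.DataFrame(self.values, index=self.tree_ids)
        df.index.name = "tree"
        df.to_csv(path_or_handle, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path_or_handle) -> "SiteLikelihoodMatrix":
        df = pd.read_csv(path_or_handle, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.values)

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()
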