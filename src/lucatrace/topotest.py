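"""Likelihood-based tree-selection tests on RELL-resampled site log-likelihoods.

Given per-site log-likelihoods for a set of candidate topologies (typically
the inferred tree and a domain-monophyly-constrained rearrangement of it),
this module runs the standard battery used to decide whether the constraint
can be rejected: Kishino-Hasegawa (KH) and its weighted variant, the
simultaneous Shimodaira-Hasegawa (SH) test and its weighted variant,
Expected Likelihood Weights (ELW), and the Approximately Unbiased (AU)
test via the multiscale bootstrap. All resampling is RELL: site
log-likelihoods are resampled, never recomputed.

A classic Felsenstein bootstrap (resample columns, rebuild the tree,
count bipartitions) is provided for branch support.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from .align import Alignment
from .phylo import SiteLikelihoodMatrix, distance_matrix, nj_tree
from .treemetrics import edge_bipartitions, is_monophyletic, minimal_clade_count, tip_labels

logger = logging.getLogger(__name__)

DEFAULT_B = 10_000          # RELL resamplings (pipeline default)
DEFAULT_BOOTSTRAP_B = 1_000  # classic bootstrap replicates
DEFAULT_AU_SCALES = tuple(np.round(np.linspace(0.5, 1.4, 10), 10))

__all__ = [
    "TopologyTestResult",
    "constrain_monophyly",
    "rell_resample",
    "kh_sh_elw",
    "au_test",
    "run_test_battery",
    "felsenstein_bootstrap",
]


# ----------------------------------------------------------------------
# Result container
# ----------------------------------------------------------------------

@dataclass
class TopologyTestResult:
    """Per-tree log-likelihoods, test p-values and ELW weights.

    ``table`` has one row per tree: total logL, delta logL versus the best
    tree, p_KH, p_wKH, p_SH, p_wSH, elw, and (when the AU test was run)
    p_AU. ELW weights sum to one across trees.
    """

    table: pd.DataFrame
    B: int
    seed: int
    au_scales: tuple[float, ...] | None = None
    notes: list[str] = field(default_factory=list)

    def pvalues_for(self, tree_id: str) -> dict[str, float]:
        """Rejection-relevant quantities for one tree (p-values plus the
        ELW weight, which plays the same role in the verdict rule)."""
        row = self.table.loc[tree_id]
        out = {}
        for col in ("p_kh", "p_wkh", "p_sh", "p_wsh", "elw", "p_au"):
            if col in row.index and np.isfinite(row[col]):
                out[col] = float(row[col])
        return out

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "B": self.B,
            "seed": self.seed,
            "au_scales": list(self.au_scales) if self.au_scales else None,
            "notes": self.notes,
            "trees": json.loads(self.table.to_json(orient="index")),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path_or_handle) -> None:
        self.table.to_csv(path_or_handle, sep="\t", float_format="%.6g")


# ----------------------------------------------------------------------
# Constrained-topology construction
# ----------------------------------------------------------------------

def constrain_monophyly(
    tree: dendropy.Tree, domain_map: dict[str, str]
) -> dendropy.Tree:
    """Minimal-disturbance rearrangement enforcing domain monophyly.

    Tips outside their domain's largest minimal clade are pruned and
    regrafted next to the patristically nearest kept tip of the same
    domain (attachment halves the target pendant edge; the moved tip keeps
    its pendant length). Already-monophyletic trees are returned unchanged
    (a copy); a domain with fewer than two tips makes monophyly vacuous.
    """
    work = tree.clone(depth=1)
    tips = tip_labels(work)
    domains = sorted({domain_map[t] for t in tips})
    if len(domains) != 2:
        raise ValueError("exactly two domain labels required")
    by_domain = {d: {t for t in tips if domain_map[t] == d} for d in domains}
    if any(len(m) < 2 for m in by_domain.values()):
        logger.info("a domain has < 2 tips; monophyly vacuous, tree unchanged")
        return work

    report = minimal_clade_count(work, domain_map)
    if all(report.monophyletic.values()):
        return work

    # patristic distances on the original tree decide attachment targets
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}

    kept: dict[str, set[str]] = {}
    offenders: list[str] = []
    for dom in domains:
        clades = report.memberships[dom]
        largest = max(clades, key=len) if clades else frozenset()
        kept[dom] = set(largest)
        offenders.extend(sorted(set(by_domain[dom]) - set(largest)))

    logger.info(
        "constraining monophyly: pruning and regrafting %d tips", len(offenders)
    )
    for label in offenders:
        dom = domain_map[label]
        target_label = min(
            kept[dom],
            key=lambda k: (pdm.patristic_distance(taxa[label], taxa[k]), k),
        )
        # prune
        leaf = next(
            l for l in work.leaf_node_iter() if l.taxon.label == label
        )
        pendant = leaf.edge.length or 0.0
        parent = leaf.parent_node
        parent.remove_child(leaf)
        work.suppress_unifurcations()
        # regraft onto the midpoint of the target tip's pendant edge
        target = next(
            l for l in work.leaf_node_iter() if l.taxon.label == target_label
        )
        t_parent = target.parent_node
        t_len = target.edge.length or 0.0
        t_parent.remove_child(target)
        joint = dendropy.Node()
        t_parent.add_child(joint)
        joint.edge.length = t_len / 2.0
        joint.add_child(target)
        target.edge.length = t_len / 2.0
        new_leaf = dendropy.Node()
        new_leaf.taxon = leaf.taxon
        joint.add_child(new_leaf)
        new_leaf.edge.length = pendant
        kept[dom].add(label)

    assert is_monophyletic(work, by_domain[domains[0]]), "constraint failed"
    return work


# ----------------------------------------------------------------------
# RELL machinery
# ----------------------------------------------------------------------

def rell_resample(
    matrix: SiteLikelihoodMatrix | np.ndarray,
    B: int,
    scale: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """RELL bootstrap: (B, n_trees) totals of resampled site logLs.

    Each replicate draws ``round(scale * n_sites)`` site indices with
    replacement and sums the stored per-site log-likelihoods; nothing is
    re-optimised. Deterministic under a fixed seed.
    """
    values = matrix.values if isinstance(matrix, SiteLikelihoodMatrix) else np.asarray(matrix)
    if values.size == 0:
        raise ValueError("empty site log-likelihood matrix")
    if B < 1 or scale <= 0:
        raise ValueError("B must be >= 1 and scale > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_sites = values.shape[1]
    m = max(1, int(round(scale * n_sites)))
    totals = np.empty((B, values.shape[0]))
    chunk = max(1, int(5e6) // max(m, 1))
    for start in range(0, B, chunk):
        stop = min(B, start + chunk)
        idx = rng.integers(0, n_sites, size=(stop - start, m))
        totals[start:stop] = values[:, idx].sum(axis=2).T
    return totals


def kh_sh_elw(
    matrix: SiteLikelihoodMatrix,
    B: int = DEFAULT_B,
    seed: int = 0,
    two_sided: bool = False,
) -> TopologyTestResult:
    """KH, weighted KH, SH, weighted SH and ELW from one RELL pass.

    KH compares each tree to the maximum-likelihood tree with a centered
    RELL null (one-sided by default); the weighted variants standardise the
    per-site log-likelihood differences by their standard deviation. SH
    compares each tree to the per-replicate maximum after centering every
    tree at its own expectation. ELW averages the per-replicate normalised
    likelihood weights.
    """
    if matrix.n_trees < 2:
        raise ValueError("need at least two trees")
    values = matrix.values
    n_trees, n_sites = values.shape
    totals = matrix.totals
    best = int(np.argmax(totals))
    notes: list[str] = []

    rng = np.random.default_rng(seed)
    resampled = rell_resample(matrix, B=B, scale=1.0, rng=rng)
    # center every tree at its observed total (the RELL expectation), so the
    # same joint draw serves KH and SH; SH >= KH then holds replicate-wise
    centered = resampled - totals[None, :]  # (B, trees)

    # pairwise standard deviations of the per-site logL differences
    sd_pair = np.ones((n_trees, n_trees))
    for j in range(n_trees):
        for k in range(j + 1, n_trees):
            s = (values[j] - values[k]).std(ddof=1) * np.sqrt(n_sites)
            sd_pair[j, k] = sd_pair[k, j] = s if s > 0 else 1.0

    # --- KH / wKH (pairwise vs the ML tree, centered null) ---
    p_kh = np.ones(n_trees)
    p_wkh = np.ones(n_trees)
    for k in range(n_trees):
        if k == best:
            continue
        if np.allclose(values[best], values[k]):
            notes.append(
                f"trees {matrix.tree_ids[best]!r} and {matrix.tree_ids[k]!r} "
                "have identical site log-likelihoods; p = 1"
            )
            logger.info(notes[-1])
            continue
        null = centered[:, best] - centered[:, k]
        obs = totals[best] - totals[k]
        if two_sided:
            p_kh[k] = float(np.mean(np.abs(null) >= abs(obs)))
        else:
            p_kh[k] = float(np.mean(null >= obs))
        # weighted variant: the reference tree is the one maximising the
        # standardised observed difference (coincides with KH for 2 trees)
        std_obs = (totals - totals[k]) / sd_pair[:, k]
        std_obs[k] = -np.inf
        j_star = int(np.argmax(std_obs))
        null_w = (centered[:, j_star] - centered[:, k]) / sd_pair[j_star, k]
        obs_w = std_obs[j_star]
        if two_sided:
            p_wkh[k] = float(np.mean(np.abs(null_w) >= abs(obs_w)))
        else:
            p_wkh[k] = float(np.mean(null_w >= obs_w))

    # --- SH / wSH (simultaneous comparison to the per-replicate maximum) ---
    delta_null = centered.max(axis=1, keepdims=True) - centered   # (B, trees)
    delta_obs = totals.max() - totals                              # (trees,)
    p_sh = np.asarray(
        (delta_null >= delta_obs[None, :]).mean(axis=0), dtype=float
    )
    p_wsh = np.empty(n_trees)
    for k in range(n_trees):
        null_w = ((centered - centered[:, [k]]) / sd_pair[None, :, k]).max(axis=1)
        obs_w = ((totals - totals[k]) / sd_pair[:, k]).max()
        p_wsh[k] = float(np.mean(null_w >= obs_w))

    # --- ELW ---
    shifted = resampled - resampled.max(axis=1, keepdims=True)
    weights = np.exp(shifted)
    weights /= weights.sum(axis=1, keepdims=True)
    elw = weights.mean(axis=0)

    table = pd.DataFrame(
        {
            "logL": totals,
            "delta_logL": totals.max() - totals,
            "p_kh": p_kh,
            "p_wkh": p_wkh,
            "p_sh": p_sh,
            "p_wsh": p_wsh,
            "elw": elw,
        },
        index=pd.Index(matrix.tree_ids, name="tree"),
    )
    return TopologyTestResult(table=table, B=B, seed=seed, notes=notes)


def au_test(
    matrix: SiteLikelihoodMatrix,
    B_per_scale: int = 2_000,
    scales: tuple[float, ...] = DEFAULT_AU_SCALES,
    seed: int = 0,
) -> pd.Series:
    """Approximately Unbiased test via the multiscale RELL bootstrap.

    For each scale r the bootstrap proportion BP_r (how often each tree is
    the replicate maximum) is computed; the signed distance d and curvature
    c are fitted by weighted least squares on
    ``Phi^-1(1 - BP_r) = d * sqrt(r) + c / sqrt(r)`` with binomial weights,
    and ``p_AU = 1 - Phi(d - c)``. BP of 0 or 1 gets a 0.5/B continuity
    correction; a degenerate fit falls back to the mean BP with a warning.
    """
    if matrix.n_trees < 2:
        raise ValueError("need at least two trees")
    if len(scales) < 3 or min(scales) >= 1.0 or max(scales) <= 1.0:
        raise ValueError("need >= 3 scales spanning values below and above 1")
    rng = np.random.default_rng(seed)
    n_trees = matrix.n_trees
    bp = np.zeros((len(scales), n_trees))
    for si, r in enumerate(scales):
        totals = rell_resample(matrix, B=B_per_scale, scale=float(r), rng=rng)
        mx = totals.max(axis=1, keepdims=True)
        ties = totals >= mx - 1e-9  # split exact ties evenly
        bp[si] = (ties / ties.sum(axis=1, keepdims=True)).mean(axis=0)

    eps = 0.5 / B_per_scale
    bp_c = np.clip(bp, eps, 1.0 - eps)
    p_au = np.empty(n_trees)
    sqrt_r = np.sqrt(np.asarray(scales, dtype=float))
    for k in range(n_trees):
        if np.allclose(bp[:, k], bp[0, k]):
            p_au[k] = float(bp[:, k].mean())
            logger.warning(
                "AU fit degenerate for tree %s; reporting raw BP",
                matrix.tree_ids[k],
            )
            continue
        y = norm.ppf(1.0 - bp_c[:, k])
        dens = norm.pdf(y)
        var = bp_c[:, k] * (1.0 - bp_c[:, k]) / (B_per_scale * dens**2)
        w = 1.0 / var
        x = np.column_stack([sqrt_r, 1.0 / sqrt_r])
        xtw = x.T * w
        beta = np.linalg.solve(xtw @ x, xtw @ y)
        d_hat, c_hat = beta
        p_au[k] = float(1.0 - norm.cdf(d_hat - c_hat))
    return pd.Series(p_au, index=pd.Index(matrix.tree_ids, name="tree"), name="p_au")


def run_test_battery(
    matrix: SiteLikelihoodMatrix,
    B: int = DEFAULT_B,
    seed: int = 0,
    au_B_per_scale: int | None = None,
    au_scales: tuple[float, ...] = DEFAULT_AU_SCALES,
) -> TopologyTestResult:
    """KH/wKH/SH/wSH/ELW plus the AU test, as one result table."""
    result = kh_sh_elw(matrix, B=B, seed=seed)
    per_scale = au_B_per_scale if au_B_per_scale is not None else max(1, B // 5)
    result.table["p_au"] = au_test(
        matrix, B_per_scale=per_scale, scales=au_scales, seed=seed + 1
    )
    result.au_scales = tuple(float(s) for s in au_scales)
    return result


# ----------------------------------------------------------------------
# Classic Felsenstein bootstrap
# ----------------------------------------------------------------------

def felsenstein_bootstrap(
    aln: Alignment,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
    tree_builder=None,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Column-resampling bootstrap support for the builder's tree.

    ``tree_builder`` maps an Alignment to a dendropy tree (default:
    neighbor joining on Poisson-corrected distances). Support values are
    the fraction of replicate trees containing each bipartition of the
    original tree, and are written onto its internal-edge labels.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tree_builder is None:
        def tree_builder(a: Alignment) -> dendropy.Tree:
            return nj_tree(distance_matrix(a))

    rng = np.random.default_rng(seed)
    base_tree = tree_builder(aln)
    all_tips = frozenset(tip_labels(base_tree))

    def normalised_biparts(tree: dendropy.Tree) -> set[frozenset]:
        out = set()
        for _edge, side in edge_bipartitions(tree):
            if 1 < len(side) < len(all_tips) - 1:
                out.add(min(side, all_tips - side, key=sorted))
        return out

    target = normalised_biparts(base_tree)
    counts = {bp: 0 for bp in target}
    for _ in range(B):
        idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
        boot = Alignment(aln.ids, aln.matrix[:, idx])
        for bp in normalised_biparts(tree_builder(boot)):
            if bp in counts:
                counts[bp] += 1
    support = {bp: c / B for bp, c in counts.items()}

    for node in base_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(side, all_tips - side, key=sorted)
        if key in support:
            node.label = f"{support[key]:.3f}"
    return base_tree, support
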