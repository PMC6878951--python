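"""Tree-reading statistics for the gene-origin question.

A gene family present in the last universal common ancestor is expected to
show (i) monophyletic archaeal and bacterial clades and (ii) a long stem
branch between the two domain crowns, mirroring universal marker proteins.
This module computes those statistics on unrooted trees and combines them
(together with the topology-test battery) into an explicit verdict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARCHAEA = "ARCHAEA"
BACTERIA = "BACTERIA"
OUTGROUP = "OUTGROUP"

__all__ = [
    "CladeReport",
    "StemStats",
    "RootPlacement",
    "Verdict",
    "VerdictThresholds",
    "is_monophyletic",
    "minimal_clade_count",
    "stem_stats",
    "root_with_outgroup",
    "luca_verdict",
]


# ----------------------------------------------------------------------
# Basic unrooted-tree helpers
# ----------------------------------------------------------------------

def tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def edge_bipartitions(tree: dendropy.Tree) -> list[tuple[dendropy.Edge, frozenset]]:
    """(edge, child-side leaf set) for every edge with a parented child."""
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        out.append((node.edge, leaves))
    return out


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    labels = sorted(tip_labels(tree))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
    return pd.DataFrame(d, index=labels, columns=labels)


def is_monophyletic(tree: dendropy.Tree, label_set: set[str]) -> bool:
    """True iff some edge bipartition equals {label_set, complement}."""
    tips = tip_labels(tree)
    label_set = set(label_set)
    unknown = label_set - tips
    if unknown:
        raise ValueError(f"unknown tip labels: {sorted(unknown)}")
    if not label_set or label_set == tips:
        raise ValueError("label set must be a non-empty proper subset of tips")
    target = frozenset(label_set)
    complement = frozenset(tips - label_set)
    for _edge, side in edge_bipartitions(tree):
        if side == target or side == complement:
            return True
    return False


# ----------------------------------------------------------------------
# Minimal clade counts (two-state parsimony)
# ----------------------------------------------------------------------

@dataclass
class CladeReport:
    """Per-domain monophyly and minimal clade decomposition.

    ``clade_counts`` maps each domain to the clade count of the canonical
    optimal labeling; ``count_options`` lists every (archaea, bacteria)
    count pair achievable at the parsimony minimum (ties are reported, not
    resolved). ``sum(counts) == parsimony_changes + 1`` always holds.
    """

    domains: tuple[str, str]
    parsimony_changes: int
    clade_counts: dict[str, int]
    count_options: list[dict[str, int]]
    memberships: dict[str, list[frozenset]]
    monophyletic: dict[str, bool]
    taxon_set: frozenset = field(init=False)

    def __post_init__(self) -> None:
        self.taxon_set = frozenset().union(*(t for m in self.memberships.values() for t in m))


def minimal_clade_count(tree: dendropy.Tree, domain_map: dict[str, str]) -> CladeReport:
    """Minimum label changes s over all internal labelings (two domains).

    Deleting the s change-edges yields s + 1 monochromatic components;
    these are the minimal clades, reported per domain with memberships.
    Tied optima (different per-domain splits of s + 1) are all reported in
    ``count_options``; memberships come from the canonical labeling with
    the smallest first-domain count.
    """
    tips = sorted(tip_labels(tree))
    if len(tips) < 2:
        raise ValueError("tree must have at least two tips")
    missing = [t for t in tips if t not in domain_map]
    if missing:
        raise ValueError(f"tips without domain label: {missing}")
    domains = sorted({domain_map[t] for t in tips})
    if len(domains) != 2:
        raise ValueError("exactly two domain labels required on the tree")
    dom_a = domains[0]

    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    children = [[index[id(c)] for c in nd.child_nodes()] for nd in nodes]

    def edge_terms(color: int, cu: int) -> tuple[int, int]:
        """(change cost, first-domain component merge) for a parent-child edge."""
        return (1 if cu != color else 0, 1 if (cu == 0 and color == 0) else 0)

    # f[i][color]: set of achievable (cost, countA) for the subtree of i
    # with node i fixed to `color`; countA counts node/edge contributions
    # (#A-nodes - #A-A-edges) inside the subtree.
    f: list[dict[int, set[tuple[int, int]]]] = [None] * len(nodes)
    # suffix[i][color][k]: achievable sums over children[i][k:]
    suffix: list[dict[int, list[set]]] = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if not children[i]:
            color = 0 if domain_map[nd.taxon.label] == dom_a else 1
            f[i] = {color: {(0, 1 if color == 0 else 0)}}
            continue
        f[i], suffix[i] = {}, {}
        for color in (0, 1):
            suf: list[set] = [None] * (len(children[i]) + 1)
            suf[-1] = {(0, 0)}
            for k in range(len(children[i]) - 1, -1, -1):
                u = children[i][k]
                opts = set()
                for cu, table in f[u].items():
                    ec, em = edge_terms(color, cu)
                    for (cost_u, a_u) in table:
                        for (cost, a) in suf[k + 1]:
                            opts.add((cost + cost_u + ec, a + a_u - em))
                suf[k] = opts
            base_a = 1 if color == 0 else 0
            f[i][color] = {(c, a + base_a) for (c, a) in suf[0]}
            suffix[i][color] = suf

    root = len(nodes) - 1
    best_cost = min(cost for tbl in f[root].values() for (cost, _a) in tbl)
    achievable_a = sorted({
        a for tbl in f[root].values() for (cost, a) in tbl if cost == best_cost
    })
    count_options = [
        {dom_a: a, domains[1]: best_cost + 1 - a} for a in achievable_a
    ]

    # canonical labeling: minimal first-domain count, then color order
    target_a = achievable_a[0]
    colors: list[int | None] = [None] * len(nodes)

    def assign(i: int, color: int, target: tuple[int, int]) -> None:
        colors[i] = color
        if not children[i]:
            return
        base_a = 1 if color == 0 else 0
        remaining = (target[0], target[1] - base_a)
        for k, u in enumerate(children[i]):
            done = False
            for cu in sorted(f[u]):
                ec, em = edge_terms(color, cu)
                for (cost_u, a_u) in sorted(f[u][cu]):
                    rest = (remaining[0] - cost_u - ec, remaining[1] - a_u + em)
                    if rest in suffix[i][color][k + 1]:
                        assign(u, cu, (cost_u, a_u))
                        remaining = rest
                        done = True
                        break
                if done:
                    break
            assert done, "clade-count backtrack failed"

    root_color = next(
        c for c in (0, 1) if (best_cost, target_a) in f[root].get(c, set())
    )
    assign(root, root_color, (best_cost, target_a))

    # components of the canonical labeling
    parent_of = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        for u in children[i]:
            parent_of[u] = i
    comp = list(range(len(nodes)))

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for i in range(len(nodes)):
        p = parent_of[i]
        if p is not None and colors[i] == colors[p]:
            comp[find(i)] = find(p)
    groups: dict[int, list[str]] = {}
    for i, nd in enumerate(nodes):
        if not children[i]:
            groups.setdefault(find(i), []).append(nd.taxon.label)
    memberships: dict[str, list[frozenset]] = {domains[0]: [], domains[1]: []}
    for rep, members in groups.items():
        dom = dom_a if colors[rep] == 0 else domains[1]
        memberships[dom].append(frozenset(members))
    for dom in memberships:
        memberships[dom].sort(key=lambda s: (-len(s), sorted(s)))
    clade_counts = {d: len(memberships[d]) for d in domains}

    # monophyly is a bipartition property; a connected backbone component
    # (count 1) with the other domain hanging off it is NOT monophyletic
    tipsets = {d: {t for t in tips if domain_map[t] == d} for d in domains}
    monophyletic = {d: is_monophyletic(tree, tipsets[d]) for d in domains}

    return CladeReport(
        domains=(domains[0], domains[1]),
        parsimony_changes=best_cost,
        clade_counts=clade_counts,
        count_options=count_options,
        memberships=memberships,
        monophyletic=monophyletic,
    )


# ----------------------------------------------------------------------
# Stem / crown statistics
# ----------------------------------------------------------------------

@dataclass
class StemStats:
    """Interdomain stem statistics; monophyly-dependent fields are None
    (and flagged) when either domain is paraphyletic."""

    both_monophyletic: bool
    stem_length: float | None
    crown_depths: dict[str, float] | None
    stem_ratio: float | None
    separation_score: float | None
    notes: list[str] = field(default_factory=list)


def _unrooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    work = tree.clone(depth=1)
    if len(work.seed_node.child_nodes()) == 2:
        work.deroot()
    work.is_rooted = False
    return work


def stem_stats(tree: dendropy.Tree, domain_map: dict[str, str]) -> StemStats:
    """Stem length, crown depths and their ratio; fallback separation score
    (mean between-domain minus mean within-domain patristic distance) when
    either domain is paraphyletic."""
    work = _unrooted_copy(tree)
    tips = tip_labels(work)
    by_domain: dict[str, set[str]] = {}
    for t in tips:
        by_domain.setdefault(domain_map[t], set()).add(t)
    if len(by_domain) != 2:
        raise ValueError("both domains must be present")
    (dom_a, set_a), (dom_b, set_b) = sorted(by_domain.items())

    mono = is_monophyletic(work, set_a)  # on an unrooted tree this covers both
    if not mono:
        pdm = patristic_distances(work)
        la, lb = sorted(set_a), sorted(set_b)
        between = pdm.loc[la, lb].values.mean()
        within_vals = []
        for labs in (la, lb):
            if len(labs) > 1:
                block = pdm.loc[labs, labs].values
                within_vals.append(block[np.triu_indices(len(labs), 1)])
        within = float(np.concatenate(within_vals).mean()) if within_vals else 0.0
        return StemStats(
            both_monophyletic=False,
            stem_length=None,
            crown_depths=None,
            stem_ratio=None,
            separation_score=float(between - within),
            notes=["domains paraphyletic; stem statistics undefined"],
        )

    stem_edge, stem_side = None, None
    for edge, side in edge_bipartitions(work):
        if side == frozenset(set_a) or side == frozenset(set_b):
            stem_edge, stem_side = edge, side
            break
    stem_length = float(stem_edge.length or 0.0)

    # crown depth: mean path length from each tip to the stem endpoint on
    # its own side
    child = stem_edge.head_node  # node on the 'side' of the bipartition
    parent = stem_edge.tail_node
    depths: dict[str, float] = {}
    for dom, members, anchor in (
        (dom_a if stem_side == frozenset(set_a) else dom_b, stem_side, child),
        (dom_b if stem_side == frozenset(set_a) else dom_a, tips - stem_side, parent),
    ):
        dist: dict[int, float] = {id(anchor): 0.0}
        total, count = 0.0, 0
        stack = [anchor]
        seen = {id(anchor), id(child if anchor is parent else parent)}
        while stack:
            nd = stack.pop()
            neighbours = list(nd.child_nodes())
            if nd.parent_node is not None:
                neighbours.append(nd.parent_node)
            for nb in neighbours:
                if id(nb) in seen:
                    continue
                seen.add(id(nb))
                edge_len = (nb.edge.length or 0.0) if nb.parent_node is nd else (nd.edge.length or 0.0)
                dist[id(nb)] = dist[id(nd)] + edge_len
                if nb.is_leaf():
                    total += dist[id(nb)]
                    count += 1
                stack.append(nb)
        depths[dom] = total / count if count else 0.0

    mean_crown = float(np.mean(list(depths.values())))
    notes: list[str] = []
    if mean_crown == 0.0:
        ratio = math.inf
        notes.append("zero crown depth; ratio reported as +inf")
    else:
        ratio = stem_length / mean_crown
    return StemStats(
        both_monophyletic=True,
        stem_length=stem_length,
        crown_depths=depths,
        stem_ratio=float(ratio),
        separation_score=None,
        notes=notes,
    )


# ----------------------------------------------------------------------
# Outgroup rooting
# ----------------------------------------------------------------------

@dataclass
class RootPlacement:
    category: str  # WITHIN_BACTERIAL_CLADE | WITHIN_ARCHAEAL_CLADE | BETWEEN_DOMAINS
    clade_entered: frozenset | None
    attachment_bipartition: frozenset
    outgroup_monophyletic: bool
    notes: list[str] = field(default_factory=list)


def root_with_outgroup(
    tree: dendropy.Tree,
    outgroup_labels: set[str],
    domain_map: dict[str, str],
) -> tuple[dendropy.Tree, RootPlacement]:
    """Root on the edge joining the outgroup to the ingroup and classify
    where the root enters the ingroup's domain structure.

    A polyphyletic outgroup is tolerated: the largest pure-outgroup clade
    is used, with a warning.
    """
    work = _unrooted_copy(tree)
    tips = tip_labels(work)
    outgroup_labels = set(outgroup_labels)
    if not outgroup_labels <= tips:
        raise ValueError("outgroup labels missing from tree")
    if outgroup_labels == tips:
        raise ValueError("outgroup cannot contain all tips")

    notes: list[str] = []
    mono = is_monophyletic(work, outgroup_labels)
    best_edge, best_side = None, frozenset()
    for edge, side in edge_bipartitions(work):
        for cand in (side, frozenset(tips) - side):
            if cand <= outgroup_labels and len(cand) > len(best_side):
                if cand == side:
                    best_edge, best_side = edge, side
                else:
                    best_edge, best_side = edge, cand
    if not mono:
        notes.append(
            f"outgroup polyphyletic; rooting on largest pure component "
            f"({len(best_side)}/{len(outgroup_labels)} tips)"
        )
        logger.warning(notes[-1])

    ingroup = tips - outgroup_labels
    # classify by the split of the ingroup at the attachment point
    attach_node = (
        best_edge.tail_node
        if frozenset(l.taxon.label for l in best_edge.head_node.leaf_iter()) == best_side
        else best_edge.head_node
    )

    length = best_edge.length or 0.0
    work.reroot_at_edge(best_edge, length1=length / 2.0, length2=length / 2.0)
    work.is_rooted = True

    # components of the ingroup around the attachment node
    comps: list[set[str]] = []
    neighbours = list(attach_node.child_nodes())
    if attach_node.parent_node is not None:
        neighbours.append(attach_node.parent_node)
    for nb in neighbours:
        comp: set[str] = set()
        stack = [(nb, attach_node)]
        while stack:
            nd, prev = stack.pop()
            if nd.is_leaf():
                comp.add(nd.taxon.label)
            nxt = list(nd.child_nodes())
            if nd.parent_node is not None:
                nxt.append(nd.parent_node)
            for other in nxt:
                if other is not prev:
                    stack.append((other, nd))
        comp &= ingroup
        if comp:
            comps.append(comp)

    domset = lambda c: {domain_map[t] for t in c}
    pure = [c for c in comps if len(domset(c)) == 1]
    if len(comps) >= 2 and all(len(domset(c)) == 1 for c in comps) and len(
        {next(iter(domset(c))) for c in comps}
    ) == 2:
        category = "BETWEEN_DOMAINS"
        clade = None
    else:
        mixed = [c for c in comps if len(domset(c)) > 1]
        if pure and mixed:
            # attachment splits off a pure sub-clade inside that domain
            target = max(pure, key=len)
            dom = next(iter(domset(target)))
            category = (
                "WITHIN_ARCHAEAL_CLADE" if dom == ARCHAEA else "WITHIN_BACTERIAL_CLADE"
            )
            clade = frozenset(target)
        else:
            smallest = min(comps, key=len)
            counts = pd.Series([domain_map[t] for t in smallest]).value_counts()
            dom = counts.index[0]
            category = (
                "WITHIN_ARCHAEAL_CLADE" if dom == ARCHAEA else "WITHIN_BACTERIAL_CLADE"
            )
            clade = frozenset(smallest)
            notes.append("ambiguous attachment (both sides mixed); majority rule used")
    placement = RootPlacement(
        category=category,
        clade_entered=clade,
        attachment_bipartition=frozenset(min(comps, key=len)) if comps else frozenset(),
        outgroup_monophyletic=mono,
        notes=notes,
    )
    return work, placement


# ----------------------------------------------------------------------
# Verdict
# ----------------------------------------------------------------------

@dataclass
class VerdictThresholds:
    alpha: float = 0.05
    stem_ratio_factor: float = 0.25  # gene stem ratio vs marker stem ratio


@dataclass
class Verdict:
    verdict: str  # CONSISTENT_WITH_LUCA | POST_LUCA_ORIGIN | INDETERMINATE
    evidence: pd.DataFrame
    thresholds: VerdictThresholds

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "thresholds": {
                "alpha": self.thresholds.alpha,
                "stem_ratio_factor": self.thresholds.stem_ratio_factor,
            },
            "evidence": self.evidence.to_dict(orient="records"),
        }


def luca_verdict(
    gene_clades: CladeReport,
    gene_stem: StemStats,
    marker_clades: CladeReport,
    marker_stem: StemStats,
    test_result,
    thresholds: VerdictThresholds | None = None,
    taxon_map=None,
) -> Verdict:
    """Combine monophyly, stem statistics and the topology-test battery.

    CONSISTENT_WITH_LUCA requires all of: both domains monophyletic in the
    gene tree; gene stem ratio at least ``stem_ratio_factor`` times the
    marker's stem ratio; and the monophyly-constrained topology not
    rejected by any test at alpha. POST_LUCA_ORIGIN requires monophyly to
    fail and the constrained topology to be rejected by every test.
    Anything else is INDETERMINATE. Gene and marker statistics must be
    computed on the same taxon set; ``taxon_map`` (gene tip -> marker
    taxon) lets paralogous gene copies map onto one species.
    """
    th = thresholds or VerdictThresholds()
    mapper = taxon_map or (lambda t: t)
    gene_species = {mapper(t) for t in gene_clades.taxon_set}
    if gene_species != set(marker_clades.taxon_set):
        raise ValueError("gene and marker statistics use different taxon sets")

    both_mono = all(gene_clades.monophyletic.values())
    marker_ratio = marker_stem.stem_ratio if marker_stem.both_monophyletic else None
    gene_ratio = gene_stem.stem_ratio if gene_stem.both_monophyletic else None
    ratio_required = (
        None if marker_ratio is None else th.stem_ratio_factor * marker_ratio
    )
    ratio_ok = (
        gene_ratio is not None
        and ratio_required is not None
        and gene_ratio >= ratio_required
    )

    if test_result is None:
        rejected_any = rejected_all = False
        constrained_pvals = {}
    else:
        constrained_pvals = test_result.pvalues_for("constrained")
        rejected_flags = [p < th.alpha for p in constrained_pvals.values()]
        rejected_any = any(rejected_flags)
        rejected_all = all(rejected_flags) and len(rejected_flags) > 0

    rows = [
        ("gene_domains_monophyletic", both_mono, True),
        ("gene_stem_ratio", gene_ratio, ratio_required),
        ("marker_stem_ratio", marker_ratio, None),
        ("gene_separation_score", gene_stem.separation_score, None),
        ("constrained_rejected_by_any_test", rejected_any, None),
        ("constrained_rejected_by_all_tests", rejected_all, None),
    ]
    for name, p in sorted(constrained_pvals.items()):
        rows.append((f"constrained_{name}", p, th.alpha))
    evidence = pd.DataFrame(rows, columns=["criterion", "value", "threshold"])

    if both_mono and ratio_ok and not rejected_any:
        verdict = "CONSISTENT_WITH_LUCA"
    elif (not both_mono) and rejected_all:
        verdict = "POST_LUCA_ORIGIN"
    else:
        verdict = "INDETERMINATE"
    return Verdict(verdict=verdict, evidence=evidence, thresholds=th)
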