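"""Synthetic gene histories for validating the origin-inference pipeline.

The generator produces the two study conditions the inference framework
must distinguish:

* ``VERTICAL_LUCA`` — the gene is born at the species-tree root (the
  ancestor predating the archaea/bacteria split) and descends vertically;
  its tree then mirrors the species tree, including the long interdomain
  stem branch.
* ``DOMAIN_ORIGIN_HGT`` — the gene is born on an edge inside one domain
  after the domains diverged and reaches the other domain only by
  horizontal transfer; with several transfers the two domains interleave
  in the gene tree and no long stem exists.

Species trees are ultrametric in time (Yule crowns of a chosen height
joined by a stem of chosen substitution length; per-edge rate multipliers
default to 1 so time equals expected substitutions per site). Gene
histories are simulated by an event-driven walk down the species tree;
every event (origin, transfer, duplication, split) is logged, so a replay
from the log can serve as an independent oracle. Alignments are evolved
under a Markov model without indels; hit tables and split-gene fragments
emulate the raw material of the curation stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .align import Alignment
from .seqmodels import N_STATES, SubstitutionModel, get_model
from .screen import DOMAIN_MODEL_LENGTHS, HELICASE, TOPOISOMERASE, HIT_COLUMNS

logger = logging.getLogger(__name__)

ARCHAEA = "ARCHAEA"
BACTERIA = "BACTERIA"

VERTICAL_LUCA = "VERTICAL_LUCA"
DOMAIN_ORIGIN_HGT = "DOMAIN_ORIGIN_HGT"

ROOT_EDGE = "ROOT"

__all__ = [
    "SpeciesTree",
    "ScenarioConfig",
    "ForcedTransfer",
    "GeneHistory",
    "DecoySpec",
    "simulate_species_tree",
    "simulate_gene_history",
    "evolve_sequences",
    "inject_split_genes",
    "make_hit_table",
]


# ----------------------------------------------------------------------
# Species tree
# ----------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """Two-domain species tree, ultrametric in time.

    ``tree`` is rooted at the midpoint of the interdomain stem; every node
    carries an ``age`` (time before present) and a ``rate_mult`` so that
    edge length = duration * rate_mult (expected substitutions per site).
    Edge ids are the labels of the edge's child node.
    """

    tree: dendropy.Tree
    domain_map: dict[str, str]
    stem_length: float
    crown_height: float

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self.domain_map)

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def node_by_edge(self, edge_id: str) -> dendropy.Node:
        for nd in self.tree.preorder_node_iter():
            if _node_label(nd) == edge_id:
                return nd
        raise KeyError(f"no edge with id {edge_id!r}")

    def edge_ids(self) -> list[str]:
        return [
            _node_label(nd)
            for nd in self.tree.preorder_node_iter()
            if nd.parent_node is not None
        ]

    def edge_domain(self, edge_id: str) -> str:
        """Domain of all tips below the edge (mixed edges raise)."""
        nd = self.node_by_edge(edge_id)
        doms = {self.domain_map[l.taxon.label] for l in nd.leaf_iter()}
        if len(doms) != 1:
            raise ValueError(f"edge {edge_id!r} subtends both domains")
        return doms.pop()

    def crown_root_edge(self, domain: str) -> str:
        return "ARCH_CROWN" if domain == ARCHAEA else "BACT_CROWN"

    def to_newick(self) -> str:
        from .phylo import write_newick

        return write_newick(self.tree)


def _node_label(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.taxon is not None else nd.label


def _yule_crown(n: int, prefix: str, rng: np.random.Generator) -> tuple[dendropy.Node, float]:
    """Forward-time pure-birth tree with n tips; returns (root node, depth).

    Node ``age`` fields are filled in later once the depth is rescaled.
    Internal bookkeeping uses forward time from the crown root.
    """
    root = dendropy.Node()
    root._birth = 0.0
    root._order = 0
    counter = 1
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            child = dendropy.Node()
            child._birth = t
            child._order = counter
            counter += 1
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / len(active))  # stretch to the present
    for k, leaf in enumerate(sorted(active, key=lambda nd: nd._order)):
        leaf.label = f"{prefix}{k + 1}"
    for nd in root.preorder_iter():
        del nd._order
    return root, t


def simulate_species_tree(
    n_arch: int,
    n_bact: int,
    stem_length: float,
    crown_height: float,
    seed: int,
    rate_multipliers: dict[str, float] | None = None,
) -> SpeciesTree:
    """Two Yule crowns rescaled to ``crown_height``, joined by a stem edge
    of exactly ``stem_length`` (the root sits at the stem midpoint)."""
    if n_arch < 2 or n_bact < 2:
        raise ValueError("degenerate crown: need at least 2 tips per domain")
    if stem_length < 0 or crown_height <= 0:
        raise ValueError("stem_length must be >= 0 and crown_height > 0")
    rng = np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    root.label = ROOT_EDGE
    root.age = crown_height + stem_length / 2.0

    domain_map: dict[str, str] = {}
    for prefix, crown_label, n, domain in (
        ("A", "ARCH_CROWN", n_arch, ARCHAEA),
        ("B", "BACT_CROWN", n_bact, BACTERIA),
    ):
        crown, depth = _yule_crown(n, prefix, rng)
        crown.label = crown_label
        scale = crown_height / depth
        counter = 0
        for nd in crown.preorder_iter():
            if nd.is_leaf():
                nd.age = 0.0
                taxon = taxon_ns.new_taxon(nd.label)
                domain_map[nd.label] = domain
                nd.taxon = taxon
                nd.label = None
            else:
                nd.age = crown_height - nd._birth * scale
                if nd is not crown:
                    counter += 1
                    nd.label = f"{crown_label}_n{counter}"
            del nd._birth
        root.add_child(crown)

    # edge lengths (substitutions/site) from ages and rate multipliers
    mults = rate_multipliers or {}
    for nd in tree.preorder_node_iter():
        nd.rate_mult = 1.0
        if nd.parent_node is not None:
            nd.rate_mult = float(mults.get(_node_label(nd), 1.0))
            nd.edge.length = (nd.parent_node.age - nd.age) * nd.rate_mult
    tree.is_rooted = True
    return SpeciesTree(
        tree=tree,
        domain_map=domain_map,
        stem_length=float(stem_length),
        crown_height=float(crown_height),
    )


# ----------------------------------------------------------------------
# Gene-history simulation
# ----------------------------------------------------------------------

@dataclass
class ForcedTransfer:
    """A transfer scheduled at a fixed forward time from the gene's origin
    context (time 0 = species root). Donor is a uniformly chosen carrier
    (restricted to ``donor_domain`` if set); the recipient is an edge id,
    a domain name (uniform among that domain's edges alive at the time),
    or None for any non-donor edge alive at the time."""

    time: float
    donor_domain: str | None = None
    recipient: str | None = None


@dataclass
class ScenarioConfig:
    """Parameters of one simulated origin scenario."""

    scenario: str = VERTICAL_LUCA
    origin_edge: str | None = None  # None: species root (forced for VERTICAL_LUCA)
    hgt_rate: float = 0.0           # events / lineage / unit time
    duplication_rate: float = 0.0
    split_fraction: float = 0.0
    additive: bool = False          # HGT adds a copy instead of replacing
    forced_transfers: list[ForcedTransfer] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (VERTICAL_LUCA, DOMAIN_ORIGIN_HGT):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.hgt_rate < 0 or self.duplication_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.split_fraction <= 1.0:
            raise ValueError("split_fraction must be in [0, 1]")
        if self.scenario == VERTICAL_LUCA and self.origin_edge not in (None, ROOT_EDGE):
            raise ValueError("VERTICAL_LUCA forces the origin to the species root")
        if self.scenario == DOMAIN_ORIGIN_HGT and self.origin_edge in (None, ROOT_EDGE):
            raise ValueError("DOMAIN_ORIGIN_HGT needs an origin edge below the root")


@dataclass
class Event:
    type: str  # ORIGIN | HGT | DUPLICATION | SPLIT
    donor: str | None
    recipient: str | None
    time: float  # forward time from the species root

    def as_row(self) -> dict:
        return {
            "type": self.type,
            "donor": self.donor if self.donor is not None else ".",
            "recipient": self.recipient if self.recipient is not None else ".",
            "time": self.time,
        }


@dataclass
class GeneHistory:
    """A simulated gene tree plus its generating context and event log."""

    gene_tree: dendropy.Tree
    events: list[Event]
    species_tree: SpeciesTree
    copy_map: dict[str, list[str]]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_row() for e in self.events])

    def events_to_tsv(self, path_or_handle) -> None:
        self.events_frame().to_csv(
            path_or_handle, sep="\t", index=False, float_format="%.8g"
        )


class _Copy:
    """A live gene copy: the species edge hosting it, the gene-tree node
    its current branch grows from, and the substitution length accumulated
    on that branch so far."""

    __slots__ = ("host", "gene_parent", "accum")

    def __init__(self, host: dendropy.Node, gene_parent: dendropy.Node) -> None:
        self.host = host
        self.gene_parent = gene_parent
        self.accum = 0.0

    def close_branch(self) -> dendropy.Node:
        node = dendropy.Node()
        self.gene_parent.add_child(node)
        node.edge.length = self.accum
        return node


def _alive_edges(sp: SpeciesTree, age: float) -> list[dendropy.Node]:
    """Species edges (child nodes) whose interval strictly contains age."""
    out = []
    for nd in sp.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.age < age < nd.parent_node.age:
            out.append(nd)
    return out


def simulate_gene_history(sp: SpeciesTree, cfg: ScenarioConfig) -> GeneHistory:
    """Evolve a gene down the species tree under the configured scenario.

    Transfers follow a Poisson process of rate ``hgt_rate`` per carrier
    lineage per unit time (plus any forced transfers); by default a
    transfer replaces the recipient lineage's copy, with ``additive=True``
    both are kept. Duplications copy in place. The event log is complete
    and time-ordered, so the gene tree can be reproduced from it.
    """
    rng = np.random.default_rng(cfg.seed)
    root_age = sp.root_age

    if cfg.scenario == VERTICAL_LUCA or cfg.origin_edge in (None, ROOT_EDGE):
        origin_node = sp.tree.seed_node
        origin_age = root_age
        origin_hosts = list(origin_node.child_nodes())
    else:
        origin_node = sp.node_by_edge(cfg.origin_edge)
        origin_age = float(origin_node.parent_node.age)
        origin_hosts = [origin_node]

    if (
        cfg.scenario == DOMAIN_ORIGIN_HGT
        and cfg.hgt_rate == 0
        and not cfg.forced_transfers
    ):
        logger.warning("gene confined to one domain (no transfer process)")

    gene_root = dendropy.Node()
    copies: list[_Copy] = [_Copy(h, gene_root) for h in origin_hosts]
    events: list[Event] = [
        Event("ORIGIN", None, cfg.origin_edge or ROOT_EDGE, time=root_age - origin_age)
    ]
    dead: list[dendropy.Node] = []

    pending = sorted(
        (replace(ft) for ft in cfg.forced_transfers), key=lambda ft: -ft.time
    )
    pending = [(root_age - ft.time, ft) for ft in pending]  # (age, spec), age desc
    for age, ft in pending:
        if not 0.0 < age < origin_age:
            raise ValueError(
                f"forced transfer at time {ft.time} outside the gene's lifetime"
            )
    pending.sort(key=lambda p: -p[0])

    def do_transfer(donor: _Copy, recipient_host: dendropy.Node, age: float, forced: bool) -> None:
        # replacement: kill copies currently on the recipient edge
        if not cfg.additive:
            for other in [c for c in copies if c.host is recipient_host]:
                node = other.close_branch()
                node.dead = True
                dead.append(node)
                copies.remove(other)
        fork = donor.close_branch()
        copies.remove(donor)
        copies.append(_Copy(donor.host, fork))
        copies.append(_Copy(recipient_host, fork))
        events.append(
            Event(
                "HGT",
                _node_label(donor.host),
                _node_label(recipient_host),
                time=root_age - age,
            )
        )

    current_age = origin_age
    total_rate_per_copy = cfg.hgt_rate + cfg.duplication_rate
    while copies:
        a_spec = max(c.host.age for c in copies)
        a_forced = pending[0][0] if pending else -np.inf
        if total_rate_per_copy > 0:
            a_rand = current_age - rng.exponential(
                1.0 / (total_rate_per_copy * len(copies))
            )
        else:
            a_rand = -np.inf
        next_age = max(a_spec, a_forced, a_rand)
        dt = current_age - next_age
        for c in copies:
            c.accum += dt * c.host.rate_mult
        current_age = next_age

        if a_rand > a_spec and a_rand > a_forced:
            donor = copies[int(rng.integers(len(copies)))]
            if rng.random() < cfg.hgt_rate / total_rate_per_copy:
                candidates = [
                    nd for nd in _alive_edges(sp, current_age) if nd is not donor.host
                ]
                candidates.sort(key=_node_label)
                if not candidates:
                    logger.info("transfer drawn with no coexisting recipient; skipped")
                    continue
                recipient = candidates[int(rng.integers(len(candidates)))]
                do_transfer(donor, recipient, current_age, forced=False)
            else:
                fork = donor.close_branch()
                copies.remove(donor)
                copies.append(_Copy(donor.host, fork))
                copies.append(_Copy(donor.host, fork))
                events.append(
                    Event(
                        "DUPLICATION",
                        _node_label(donor.host),
                        _node_label(donor.host),
                        time=root_age - current_age,
                    )
                )
            continue

        if a_forced > a_spec:
            _age, ft = pending.pop(0)
            donors = copies
            if ft.donor_domain is not None:
                donors = [
                    c for c in copies
                    if sp.edge_domain(_node_label(c.host)) == ft.donor_domain
                ] or copies
            donor = donors[int(rng.integers(len(donors)))]
            if ft.recipient in (ARCHAEA, BACTERIA, None):
                candidates = [
                    nd for nd in _alive_edges(sp, current_age) if nd is not donor.host
                ]
                if ft.recipient is not None:
                    candidates = [
                        nd for nd in candidates
                        if sp.edge_domain(_node_label(nd)) == ft.recipient
                    ]
                candidates.sort(key=_node_label)
                if not candidates:
                    logger.warning("forced transfer has no eligible recipient; skipped")
                    continue
                recipient = candidates[int(rng.integers(len(candidates)))]
            else:
                recipient = sp.node_by_edge(ft.recipient)
                if not recipient.age < current_age < recipient.parent_node.age:
                    raise ValueError(
                        f"forced transfer recipient {ft.recipient!r} does not "
                        f"coexist with the donor at time {ft.time}"
                    )
            do_transfer(donor, recipient, current_age, forced=True)
            continue

        # speciation (or arrival at the tips when a_spec == 0)
        if a_spec <= 0.0:
            break
        for c in [c for c in copies if c.host.age == a_spec]:
            fork = c.close_branch()
            copies.remove(c)
            for child in c.host.child_nodes():
                copies.append(_Copy(child, fork))

    # finalise tips
    taxon_ns = dendropy.TaxonNamespace()
    copy_map: dict[str, list[str]] = {}
    per_tip: dict[str, list[_Copy]] = {}
    for c in copies:
        per_tip.setdefault(c.host.taxon.label, []).append(c)
    for label in sorted(per_tip):
        group = per_tip[label]
        copy_map[label] = []
        for k, c in enumerate(group):
            leaf = c.close_branch()
            name = label if len(group) == 1 else f"{label}_copy{k + 1}"
            leaf.taxon = taxon_ns.new_taxon(name)
            copy_map[label].append(name)

    gene_tree = dendropy.Tree(taxon_namespace=taxon_ns)
    gene_tree.seed_node = gene_root
    gene_tree.is_rooted = True
    _prune_dead(gene_tree)
    events.sort(key=lambda e: e.time)
    return GeneHistory(
        gene_tree=gene_tree,
        events=events,
        species_tree=sp,
        copy_map=copy_map,
    )


def _prune_dead(tree: dendropy.Tree) -> None:
    """Remove lineages that were replaced by an incoming transfer, then
    collapse the resulting pass-through nodes."""
    changed = True
    while changed:
        changed = False
        for nd in list(tree.postorder_node_iter()):
            if nd.parent_node is None:
                continue
            if not nd.child_nodes() and (getattr(nd, "dead", False) or nd.taxon is None):
                nd.parent_node.remove_child(nd)
                changed = True
    tree.suppress_unifurcations()
    seed = tree.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        seed.remove_child(child)
        tree.seed_node = child
        seed = child


# ----------------------------------------------------------------------
# Sequence evolution
# ----------------------------------------------------------------------

def evolve_sequences(
    history: GeneHistory | dendropy.Tree,
    n_sites: int,
    model: str | SubstitutionModel = "POISSON",
    seed: int = 0,
) -> Alignment:
    """Evolve a gap-free alignment down a tree under a Markov model.

    The root sequence is drawn from the stationary distribution; each edge
    applies the transition kernel for its length. With a discrete-gamma
    model, per-site rate categories are drawn once at the root.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    tree = history.gene_tree if isinstance(history, GeneHistory) else history
    mdl = get_model(model) if isinstance(model, str) else model
    rng = np.random.default_rng(seed)

    site_rates = (
        mdl.category_rates[rng.integers(0, mdl.gamma_categories, size=n_sites)]
        if mdl.gamma_categories > 1
        else None
    )

    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(N_STATES, size=n_sites, p=mdl.pi)
    rows: list[tuple[str, np.ndarray]] = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            parent_states = states[id(nd.parent_node)]
            t = nd.edge.length or 0.0
            child = np.empty(n_sites, dtype=np.int8)
            if site_rates is None:
                p = mdl.transition_matrix(t)
                for s in range(N_STATES):
                    idx = np.flatnonzero(parent_states == s)
                    if idx.size:
                        child[idx] = rng.choice(N_STATES, size=idx.size, p=p[s])
            else:
                for rate in np.unique(site_rates):
                    p = mdl.transition_matrix(t * rate)
                    sel = site_rates == rate
                    for s in range(N_STATES):
                        idx = np.flatnonzero(sel & (parent_states == s))
                        if idx.size:
                            child[idx] = rng.choice(N_STATES, size=idx.size, p=p[s])
            states[id(nd)] = child
        if nd.is_leaf():
            rows.append((nd.taxon.label, states[id(nd)]))
    rows.sort(key=lambda r: r[0])
    ids = [r[0] for r in rows]
    return Alignment(ids, np.vstack([r[1] for r in rows]).astype(np.int8))


# ----------------------------------------------------------------------
# Split genes and hit tables
# ----------------------------------------------------------------------

def inject_split_genes(
    records: list[tuple[str, str]],
    split_fraction: float,
    seed: int = 0,
    overlap: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Replace a fraction of records by prefix/suffix fragment pairs.

    Fragment A is ``seq[:pos]`` and fragment B ``seq[pos - overlap:]``, so
    merging them with the overlap collapsed once recovers the original
    exactly. Returns the new record list and a pairing manifest
    (fragment_a, fragment_b, original_id, split_pos, overlap).
    """
    if not records:
        raise ValueError("records must be non-empty")
    if not 0.0 <= split_fraction <= 1.0:
        raise ValueError("split_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_split = int(round(split_fraction * len(records)))
    chosen = set(
        rng.choice(len(records), size=n_split, replace=False).tolist()
    ) if n_split else set()

    out: list[tuple[str, str]] = []
    rows = []
    for i, (name, seq) in enumerate(records):
        if i not in chosen:
            out.append((name, seq))
            continue
        lo = max(1, int(np.floor(0.3 * len(seq))))
        hi = max(lo + 1, int(np.ceil(0.7 * len(seq))))
        pos = int(rng.integers(lo, hi))
        if pos <= 0 or pos >= len(seq) or pos - overlap < 0:
            raise ValueError(f"split position outside sequence for {name!r}")
        frag_a, frag_b = f"{name}__frag1", f"{name}__frag2"
        out.append((frag_a, seq[:pos]))
        out.append((frag_b, seq[pos - overlap:]))
        rows.append(
            {
                "fragment_a": frag_a,
                "fragment_b": frag_b,
                "original_id": name,
                "split_pos": pos,
                "overlap": overlap,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["fragment_a", "fragment_b", "original_id", "split_pos", "overlap"]
    )
    return out, manifest


@dataclass
class DecoySpec:
    """Counts of decoy hit-table rows to fabricate."""

    helicase_only: int = 0
    topo_only: int = 0
    weak: int = 0  # two-domain records with E-values failing the cutoff


def make_hit_table(
    true_ids: list[str],
    decoy_spec: DecoySpec | dict,
    seed: int = 0,
    e_pass: float = 1e-100,
    query_id: str = "RG_profile",
) -> pd.DataFrame:
    """Fabricate a homology-hit table: genuine two-domain fusion targets
    passing the E-value cutoff plus single-domain and weak-E-value decoys
    (the dominant contaminants of a fusion-protein profile search)."""
    spec = DecoySpec(**decoy_spec) if isinstance(decoy_spec, dict) else decoy_spec
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def envelope_rows(target, evalue, bitscore, domains):
        start = int(rng.integers(1, 30))
        for label in domains:
            length = DOMAIN_MODEL_LENGTHS[label]
            span = int(round(length * rng.uniform(0.85, 1.0)))
            rows.append(
                {
                    "target": target,
                    "query": query_id,
                    "evalue": evalue,
                    "bitscore": bitscore,
                    "dom_from": start,
                    "dom_to": start + span - 1,
                    "dom_label": label,
                }
            )
            start += span + int(rng.integers(5, 40))

    log_pass = np.log10(e_pass)
    for name in true_ids:
        evalue = 10.0 ** rng.uniform(log_pass - 80, log_pass - 10)
        envelope_rows(name, evalue, rng.uniform(900, 1600), (HELICASE, TOPOISOMERASE))
    for i in range(spec.helicase_only):
        evalue = 10.0 ** rng.uniform(log_pass - 50, log_pass - 1)
        envelope_rows(f"HEL_DECOY{i + 1}", evalue, rng.uniform(300, 800), (HELICASE,))
    for i in range(spec.topo_only):
        evalue = 10.0 ** rng.uniform(log_pass - 50, log_pass - 1)
        envelope_rows(f"TOPO_DECOY{i + 1}", evalue, rng.uniform(300, 800), (TOPOISOMERASE,))
    for i in range(spec.weak):
        evalue = 10.0 ** rng.uniform(log_pass + 10, -5)
        envelope_rows(
            f"WEAK_DECOY{i + 1}", evalue, rng.uniform(100, 300), (HELICASE, TOPOISOMERASE)
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
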