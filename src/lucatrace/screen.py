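"""Candidate-sequence curation for a two-domain fusion protein.

Reverse gyrase is the fusion of an SF2-like helicase domain and a
topoisomerase 1A domain on a single polypeptide, so homology searches with
a fusion-protein profile drown in single-domain helicase and topoisomerase
hits. The curation stage reproduced here keeps a hit only if it survives a
strict E-value cutoff (1e-100 by default) AND carries both domains on one
target sequence; known split genes (two half-length ORFs in one organism)
are merged back into full-length records; the putative second zinc finger
(CxxC-x(9-11)-CxxC) is scanned for; and simple dataset summaries (mean
pairwise identity, optimum-growth-temperature fractions) are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .align import GAP, Alignment

logger = logging.getLogger(__name__)

HELICASE = "HELICASE"
TOPOISOMERASE = "TOPOISOMERASE"

DEFAULT_E_CUTOFF = 1e-100
DEFAULT_MIN_COVERAGE = 0.5
# nominal profile lengths used to express envelope coverage as a fraction
DOMAIN_MODEL_LENGTHS = {HELICASE: 400, TOPOISOMERASE: 550}
DEFAULT_OGT_THRESHOLDS = (65.0, 75.0)

__all__ = [
    "HitRecord",
    "ArchitectureCall",
    "MotifHit",
    "OgtSummary",
    "read_hit_table",
    "write_hit_table",
    "hits_from_table",
    "filter_hits",
    "classify_architecture",
    "concatenate_split",
    "scan_zn2",
    "pairwise_identity",
    "ogt_summary",
    "read_taxon_table",
]


# ----------------------------------------------------------------------
# Hit records and the tabular hit format
# ----------------------------------------------------------------------

@dataclass
class HitRecord:
    """One profile-search hit: a target sequence with one or more domain
    envelopes (1-based inclusive residue coordinates)."""

    target_id: str
    query_id: str
    evalue: float
    bitscore: float
    envelopes: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (start, end, label) in self.envelopes:
            if start > end:
                raise ValueError(
                    f"malformed envelope {start}-{end} on {self.target_id}"
                )


HIT_COLUMNS = ["target", "query", "evalue", "bitscore", "dom_from", "dom_to", "dom_label"]


def write_hit_table(table: pd.DataFrame, path_or_handle) -> None:
    """Whitespace-delimited hit table with a comment header line."""
    out = table[HIT_COLUMNS]
    header = "# " + " ".join(HIT_COLUMNS) + "\n"
    body = out.to_string(index=False, header=False, float_format=lambda v: f"{v:.6g}")
    text = header + "\n".join(line.strip() for line in body.splitlines()) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)


def read_hit_table(path_or_handle) -> pd.DataFrame:
    df = pd.read_csv(
        path_or_handle,
        sep=r"\s+",
        comment="#",
        names=HIT_COLUMNS,
        dtype={"target": str, "query": str, "dom_label": str},
    )
    return df


def hits_from_table(table: pd.DataFrame) -> list[HitRecord]:
    """Group envelope rows into one HitRecord per (target, query)."""
    records: list[HitRecord] = []
    for (target, query), grp in table.groupby(["target", "query"], sort=False):
        envelopes = [
            (int(r.dom_from), int(r.dom_to), str(r.dom_label))
            for r in grp.itertuples()
        ]
        records.append(
            HitRecord(
                target_id=str(target),
                query_id=str(query),
                evalue=float(grp.evalue.min()),
                bitscore=float(grp.bitscore.max()),
                envelopes=envelopes,
            )
        )
    return records


# ----------------------------------------------------------------------
# E-value filtering and architecture classification
# ----------------------------------------------------------------------

def filter_hits(records: list[HitRecord], e_cutoff: float = DEFAULT_E_CUTOFF) -> list[HitRecord]:
    """Keep records with evalue <= cutoff (inclusive), order preserved."""
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    for rec in records:
        if not rec.evalue > 0:
            raise ValueError(f"malformed hit: non-positive E-value on {rec.target_id}")
    return [rec for rec in records if rec.evalue <= e_cutoff]


@dataclass
class ArchitectureCall:
    """Domain-architecture call for one target sequence."""

    target_id: str
    call: str  # RG | HELICASE_ONLY | TOPO_ONLY | PARTIAL | OTHER
    coverage: dict[str, float] = field(default_factory=dict)


def classify_architecture(
    records: list[HitRecord],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    domain_lengths: dict[str, int] | None = None,
) -> list[ArchitectureCall]:
    """Call RG for targets carrying both a helicase and a topoisomerase
    envelope, each covering at least ``min_coverage`` of its profile.

    Overlapping envelopes with different labels on one target are resolved
    in favour of the higher bitscore (logged, never an error). Targets with
    a single domain are HELICASE_ONLY / TOPO_ONLY; both domains present but
    under-covered is PARTIAL; anything else OTHER.
    """
    lengths = domain_lengths or DOMAIN_MODEL_LENGTHS
    by_target: dict[str, list[HitRecord]] = {}
    for rec in records:
        by_target.setdefault(rec.target_id, []).append(rec)

    calls: list[ArchitectureCall] = []
    for target, recs in by_target.items():
        envelopes: list[tuple[int, int, str, float]] = []
        for rec in recs:
            envelopes.extend(
                (start, end, label, rec.bitscore) for (start, end, label) in rec.envelopes
            )
        # resolve overlapping envelopes of different labels by bitscore
        envelopes.sort(key=lambda e: (-e[3], e[0]))
        accepted: list[tuple[int, int, str, float]] = []
        for env in envelopes:
            clash = any(
                env[0] <= a[1] and a[0] <= env[1] and a[2] != env[2]
                for a in accepted
            )
            if clash:
                logger.info(
                    "target %s: overlapping %s envelope dropped (lower bitscore)",
                    target, env[2],
                )
                continue
            accepted.append(env)

        coverage: dict[str, float] = {}
        for (start, end, label, _score) in accepted:
            if label not in lengths:
                continue
            frac = (end - start + 1) / lengths[label]
            coverage[label] = max(coverage.get(label, 0.0), min(frac, 1.0))

        has_hel = HELICASE in coverage
        has_topo = TOPOISOMERASE in coverage
        if has_hel and has_topo:
            if (
                coverage[HELICASE] >= min_coverage
                and coverage[TOPOISOMERASE] >= min_coverage
            ):
                call = "RG"
            else:
                call = "PARTIAL"
        elif has_hel:
            call = "HELICASE_ONLY" if coverage[HELICASE] >= min_coverage else "PARTIAL"
        elif has_topo:
            call = "TOPO_ONLY" if coverage[TOPOISOMERASE] >= min_coverage else "PARTIAL"
        else:
            call = "OTHER"
        calls.append(ArchitectureCall(target_id=target, call=call, coverage=coverage))
    return calls


# ----------------------------------------------------------------------
# Split-gene concatenation
# ----------------------------------------------------------------------

def _default_organism_of(fragment_id: str) -> str:
    for marker in ("__frag", "__part"):
        if marker in fragment_id:
            return fragment_id.split(marker)[0]
    return fragment_id.rsplit("_", 1)[0]


def concatenate_split(
    fragments: list[tuple[str, str]],
    manifest: pd.DataFrame | None = None,
    architecture: dict[str, str] | None = None,
    organism_of=_default_organism_of,
    max_overlap: int = 30,
) -> list[dict]:
    """Merge split-gene fragment pairs into full-length records.

    With a manifest (columns fragment_a, fragment_b, original_id, overlap)
    the pairing and overlap are taken as given; the duplicated overlap is
    collapsed once and mismatching overlap residues raise an error naming
    the pair. Without a manifest a heuristic pairing is used (always
    logged): fragments of the same organism whose domain calls are
    complementary (one helicase-only, one topoisomerase-only) are merged,
    detecting the overlap as the longest suffix/prefix agreement up to
    ``max_overlap``.

    Returns records as dicts with keys id, sequence, concatenated.
    """
    if not fragments:
        raise ValueError("no fragments given")
    seq_of = dict(fragments)
    merged: list[dict] = []
    used: set[str] = set()

    def merge_pair(fa: str, fb: str, overlap: int, out_id: str) -> dict:
        a, b = seq_of[fa], seq_of[fb]
        if overlap < 0 or overlap > min(len(a), len(b)):
            raise ValueError(f"invalid overlap {overlap} for pair ({fa}, {fb})")
        if overlap and a[-overlap:] != b[:overlap]:
            raise ValueError(
                f"inconsistent overlap for pair ({fa}, {fb}): "
                f"{a[-overlap:]!r} != {b[:overlap]!r}"
            )
        return {
            "id": out_id,
            "sequence": a + b[overlap:],
            "concatenated": True,
        }

    if manifest is not None and len(manifest):
        for row in manifest.itertuples():
            merged.append(
                merge_pair(row.fragment_a, row.fragment_b, int(row.overlap), row.original_id)
            )
            used.update((row.fragment_a, row.fragment_b))
    elif manifest is None:
        logger.info("no split-gene manifest: using heuristic same-organism pairing")
        by_org: dict[str, list[str]] = {}
        for fid, _seq in fragments:
            by_org.setdefault(organism_of(fid), []).append(fid)
        for org, members in sorted(by_org.items()):
            if len(members) != 2:
                continue
            fa, fb = sorted(members)
            if architecture is not None:
                calls = {architecture.get(f, "OTHER") for f in (fa, fb)}
                if calls != {"HELICASE_ONLY", "TOPO_ONLY"}:
                    continue
                if architecture.get(fa) != "HELICASE_ONLY":
                    fa, fb = fb, fa
            a, b = seq_of[fa], seq_of[fb]
            overlap = 0
            for k in range(min(max_overlap, len(a), len(b)), 0, -1):
                if a[-k:] == b[:k]:
                    overlap = k
                    break
            logger.info(
                "heuristic split-gene pairing: %s + %s -> %s (overlap %d)",
                fa, fb, org, overlap,
            )
            merged.append(merge_pair(fa, fb, overlap, org))
            used.update((fa, fb))

    for fid, seq in fragments:
        if fid not in used:
            merged.append({"id": fid, "sequence": seq, "concatenated": False})
    return merged


# ----------------------------------------------------------------------
# Zn2 motif scan
# ----------------------------------------------------------------------

@dataclass
class MotifHit:
    """One CxxC-x(9-11)-CxxC match; start is the 1-based position of the
    first cysteine."""

    start: int
    spacer_length: int
    matched_text: str


def scan_zn2(sequence: str, min_spacer: int = 9, max_spacer: int = 11) -> list[MotifHit]:
    """All non-overlapping Zn2 motif matches, left to right.

    At a given start the shortest spacer wins; the scan resumes after the
    end of each accepted match, so matches never overlap.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    i = 0
    n = len(seq)
    while i + 8 + min_spacer <= n:
        matched = False
        if seq[i] == "C" and seq[i + 3] == "C":
            for spacer in range(min_spacer, max_spacer + 1):
                j = i + 4 + spacer  # first cysteine of the second CxxC
                if j + 3 < n and seq[j] == "C" and seq[j + 3] == "C":
                    hits.append(
                        MotifHit(
                            start=i + 1,
                            spacer_length=spacer,
                            matched_text=seq[i : j + 4],
                        )
                    )
                    i = j + 4
                    matched = True
                    break
        if not matched:
            i += 1
    return hits


# ----------------------------------------------------------------------
# Dataset summaries
# ----------------------------------------------------------------------

def pairwise_identity(aln: Alignment) -> float:
    """Mean pairwise percent identity over all unordered row pairs.

    Identity of a pair is matches / columns where neither row is a gap;
    pairs with no comparable columns are excluded with a warning.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least two rows")
    m = aln.matrix
    idents: list[float] = []
    skipped = 0
    for i, j in combinations(range(aln.n_sequences), 2):
        both = (m[i] != GAP) & (m[j] != GAP)
        total = int(both.sum())
        if total == 0:
            skipped += 1
            continue
        idents.append(float((m[i][both] == m[j][both]).sum()) / total)
    if skipped:
        logger.warning("%d pairs with no comparable columns excluded", skipped)
    if not idents:
        raise ValueError("no comparable pairs")
    return 100.0 * float(np.mean(idents))


@dataclass
class OgtSummary:
    """Fractions of taxa with optimum growth temperature above thresholds."""

    fractions: dict[float, float]
    below: dict[float, list[str]]
    n_with_ogt: int
    n_missing: int


def read_taxon_table(path_or_handle) -> pd.DataFrame:
    """Taxon metadata TSV: taxon_id, domain, phylum, ogt_celsius."""
    df = pd.read_csv(path_or_handle, sep="\t", dtype={"taxon_id": str})
    required = {"taxon_id", "domain"}
    if not required <= set(df.columns):
        raise ValueError(f"taxon table must contain columns {sorted(required)}")
    return df


def ogt_summary(
    taxa: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_OGT_THRESHOLDS,
) -> OgtSummary:
    """Fraction of taxa with OGT above each threshold (taxa lacking an OGT
    are excluded from the denominator and counted)."""
    if "ogt_celsius" not in taxa.columns:
        raise ValueError("taxon table has no ogt_celsius column")
    known = taxa.dropna(subset=["ogt_celsius"])
    if known.empty:
        raise ValueError("no taxa with known optimum growth temperature")
    fractions: dict[float, float] = {}
    below: dict[float, list[str]] = {}
    for th in thresholds:
        above = known["ogt_celsius"] > th
        fractions[float(th)] = float(above.mean())
        below[float(th)] = sorted(known.loc[~above, "taxon_id"].tolist())
    return OgtSummary(
        fractions=fractions,
        below=below,
        n_with_ogt=int(len(known)),
        n_missing=int(len(taxa) - len(known)),
    )
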