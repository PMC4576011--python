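"""Ortholog inference: two-round reciprocal screening, similarity-graph
construction, Markov clustering into orthogroups, relationship
classification, and annotation transfer.

The procedure mirrors the classic reference-anchored workflow for predicting
flowering-gene orthologs in cereal genomes:

1. forward search: reference flowering proteins vs each target proteome at
   ``E < 1e-5``;
2. reverse search: every hit target protein vs the reference proteome; a
   target gene is retained only if its originating reference gene ranks
   among its top-``k`` (default 3) reverse hits;
3. all retained candidates (reference + targets) enter an all-vs-all
   similarity graph (edges require ``E < 1e-5`` and a match-length
   percentage >= 50% of the shorter sequence; weight = mean of the two
   directions' ``-log10 E``, floored at ``E = 1e-300``);
4. Markov clustering (expansion power 2, inflation 1.5 by default) partitions
   the graph; clusters without a reference flowering gene are dropped, and
   the survivors become orthogroups (OGs).

Per species pair an OG is one-to-one, one-to-many, many-to-one or
many-to-many according to its member counts, and each target gene inherits
the description and functional group of its best reference hit.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import alignment
from .alignment import ScoringScheme, hit_sort_key
from .core_io import HitRecord, SequenceRecord

logger = logging.getLogger(__name__)

#: The seven flowering-pathway functional groups of the reference set.
FUNCTIONAL_GROUPS = (
    "autonomous",
    "flower development",
    "gibberellin",
    "pathway integration",
    "photoperiod",
    "regulation",
    "vernalization",
)

RELATIONSHIPS = ("one-to-one", "one-to-many", "many-to-one", "many-to-many", "absent")

_UNCHARACTERIZED_MARKERS = ("uncharacterized", "predicted protein", "unknown protein")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceGene:
    """A reference flowering gene: protein, chromosome, pathway membership.

    MicroRNA entries carry ``is_protein_coding = False`` and must be excluded
    from search input (they have no protein)."""

    gene_id: str
    functional_group: str
    chromosome: str | None = None
    protein: SequenceRecord | None = None
    is_protein_coding: bool = True
    description: str = ""

    def __post_init__(self) -> None:
        if self.is_protein_coding and self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"unknown functional group {self.functional_group!r}; "
                f"expected one of {FUNCTIONAL_GROUPS}"
            )
        if self.is_protein_coding and self.protein is None:
            raise ValueError(f"protein-coding reference gene {self.gene_id!r} needs a protein")


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over species-tagged gene ids (no self-loops)."""

    species_of: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def add_node(self, node: str, species: str) -> None:
        self.species_of[node] = species

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if weight < 0:
            raise ValueError("edge weights must be >= 0")
        self.edges[(min(u, v), max(u, v))] = float(weight)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.species_of)

    def weight_matrix(self, order: Sequence[str]) -> np.ndarray:
        index = {n: i for i, n in enumerate(order)}
        A = np.zeros((len(order), len(order)))
        for (u, v), w in self.edges.items():
            if u in index and v in index:
                A[index[u], index[v]] = A[index[v], index[u]] = w
        return A


@dataclass(frozen=True)
class ClusteringParams:
    """Markov-clustering controls.

    ``inflation`` sets cluster granularity (> 1; larger splits harder);
    expansion is a fixed matrix squaring.  ``prune_threshold`` should stay
    well below ``1 / n_nodes`` or mass pruning can disconnect real clusters.
    ``evalue_cap_exponent`` floors edge E-values at ``10**-cap`` so that
    vanishing E-values get finite weights.
    """

    inflation: float = 1.5
    expansion_power: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_epsilon: float = 1e-6
    evalue_cap_exponent: float = 300.0

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")


@dataclass
class OrthoGroup:
    """A cluster of genes spanning species, anchored on >= 1 reference gene."""

    og_id: str
    members: dict[str, list[str]]  # species -> sorted gene ids
    contains_reference_flowering_gene: bool = True

    def __post_init__(self) -> None:
        if not any(self.members.values()):
            raise ValueError(f"orthogroup {self.og_id!r} has no members")
        self.members = {sp: sorted(ids) for sp, ids in self.members.items() if ids}

    @property
    def species(self) -> list[str]:
        return sorted(self.members)

    @property
    def all_members(self) -> list[str]:
        return sorted(g for ids in self.members.values() for g in ids)

    def count(self, species: str) -> int:
        return len(self.members.get(species, []))


# ---------------------------------------------------------------------------
# Reciprocal screening
# ---------------------------------------------------------------------------


def collapse_best_hits(hits: Iterable[HitRecord]) -> dict[tuple[str, str], HitRecord]:
    """Collapse multiple HSPs per (query, subject) gene pair to the best one
    (lowest E, then highest bit score)."""
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in best or hit_sort_key(h) < hit_sort_key(best[key]):
            best[key] = h
    return best


def rank_hits_per_query(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    """Per-query hit lists sorted by the total tie-break (E, -bit, subject)."""
    best = collapse_best_hits(hits)
    per_query: dict[str, list[HitRecord]] = defaultdict(list)
    for h in best.values():
        per_query[h.query_id].append(h)
    return {q: sorted(hs, key=hit_sort_key) for q, hs in per_query.items()}


def reciprocal_filter(
    forward_hits: Iterable[HitRecord],
    reverse_hits: Iterable[HitRecord],
    k: int = 3,
) -> dict[str, set[str]]:
    """Second-round retention rule.

    A target gene ``t`` hit by reference gene ``r`` in the forward search is
    retained iff ``r`` appears among the top-``k`` ranked reverse hits of
    ``t`` (distinct subject genes, ranked by E-value with the documented
    tie-break).  Targets with no reverse hits at all are rejected.  Returns
    ``{reference_gene: {retained target genes}}``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked_reverse = rank_hits_per_query(reverse_hits)
    retained: dict[str, set[str]] = defaultdict(set)
    for (r, t), _hit in collapse_best_hits(forward_hits).items():
        top = ranked_reverse.get(t, [])[:k]
        if any(h.subject_id == r for h in top):
            retained[r].add(t)
    return dict(retained)


def match_length_percentage(hit: HitRecord, query_len: int, subject_len: int) -> float:
    """Aligned length as a percentage of the shorter sequence, capped at 100."""
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be > 0")
    return min(100.0, 100.0 * hit.alignment_length / min(query_len, subject_len))


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------


def build_graph(
    all_vs_all_hits: Iterable[HitRecord],
    sequence_lengths: Mapping[str, int],
    species_of: Mapping[str, str],
    params: ClusteringParams | None = None,
    evalue_max: float = 1e-5,
    min_match_pct: float = 50.0,
) -> SimilarityGraph:
    """Similarity graph for clustering.

    A directed hit contributes only if ``E < evalue_max`` and the
    match-length percentage (vs the shorter sequence) is >= ``min_match_pct``.
    Edge weight = mean over the contributing directions of ``-log10 E``, with
    ``E = 0`` (or below the cap) mapped to ``evalue_cap_exponent``.
    """
    params = params or ClusteringParams()
    cap = params.evalue_cap_exponent
    graph = SimilarityGraph()
    for node, sp in species_of.items():
        graph.add_node(node, sp)
    contributions: dict[tuple[str, str], list[float]] = defaultdict(list)
    for (q, s), hit in collapse_best_hits(all_vs_all_hits).items():
        if q == s or hit.evalue >= evalue_max:
            continue
        pct = match_length_percentage(hit, sequence_lengths[q], sequence_lengths[s])
        if pct < min_match_pct:
            continue
        w = cap if hit.evalue <= 10.0 ** (-cap) else min(cap, -math.log10(hit.evalue))
        contributions[(min(q, s), max(q, s))].append(w)
    for (u, v), ws in contributions.items():
        graph.add_edge(u, v, sum(ws) / len(ws))
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    dead = sums <= 0
    if dead.any():  # re-seed emptied columns on their own diagonal
        M[np.where(dead)[0], np.where(dead)[0]] = 1.0
        sums = M.sum(axis=0)
    return M / sums


def mcl_cluster(
    graph: SimilarityGraph,
    params: ClusteringParams | None = None,
    inspect: Callable[[np.ndarray], None] | None = None,
) -> list[set[str]]:
    """Markov clustering of the similarity graph into a node partition.

    Builds a column-stochastic transition matrix from edge weights with
    self-loops (loop weight = the node's maximum incident edge weight, or 1
    for isolated nodes), then iterates expansion (matrix power 2), inflation
    (entry-wise power, column renormalization) and pruning until the matrix
    is stable.  Clusters are the connected components of the converged
    matrix's support, which covers every node exactly once.

    ``inspect``, if given, is called with the column-stochastic matrix after
    every inflation step (a testing/diagnostics hook).
    """
    params = params or ClusteringParams()
    nodes = graph.nodes
    if not nodes:
        return []
    A = graph.weight_matrix(nodes)
    loop = A.max(axis=0)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(A, loop)
    M = _normalize_columns(A.astype(float))

    converged = False
    for _ in range(params.max_iterations):
        prev = M
        M = np.linalg.matrix_power(M, params.expansion_power)
        M = M ** params.inflation
        M[M < params.prune_threshold] = 0.0
        M = _normalize_columns(M)
        if inspect is not None:
            inspect(M)
        if np.abs(M - prev).max() < params.convergence_epsilon:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; using current state",
                       params.max_iterations)

    # Connected components of the converged support (symmetrized).
    support = (M > 0) | (M > 0).T
    n = len(nodes)
    seen = np.zeros(n, dtype=bool)
    clusters: list[set[str]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = {start}
        while stack:
            u = stack.pop()
            for v in np.where(support[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    comp.add(int(v))
                    stack.append(int(v))
        clusters.append({nodes[i] for i in comp})
    return clusters


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------


def assign_orthogroups(
    partition: Iterable[set[str]],
    reference_ids: Iterable[str],
    species_of: Mapping[str, str],
) -> list[OrthoGroup]:
    """Clusters holding >= 1 reference flowering gene become orthogroups.

    Clusters without any reference gene are dropped (their count is logged).
    Stable ids (``OG0001``, ...) are assigned by sorted member content, so the
    numbering is independent of clustering order.
    """
    ref = set(reference_ids)
    kept = sorted(
        (tuple(sorted(c)) for c in partition if c & ref),
    )
    dropped = sum(1 for c in partition if not (set(c) & ref))
    if dropped:
        logger.info("dropped %d clusters with no reference flowering gene", dropped)
    ogs = []
    for i, members in enumerate(kept, start=1):
        by_species: dict[str, list[str]] = defaultdict(list)
        for g in members:
            by_species[species_of[g]].append(g)
        ogs.append(OrthoGroup(og_id=f"OG{i:04d}", members=dict(by_species)))
    return ogs


def classify_relationship(og: OrthoGroup, species_pair: tuple[str, str]) -> str:
    """Orthology-relationship label for one species pair from member counts."""
    a, b = og.count(species_pair[0]), og.count(species_pair[1])
    if a == 0 or b == 0:
        return "absent"
    if a == 1 and b == 1:
        return "one-to-one"
    if a == 1:
        return "one-to-many"
    if b == 1:
        return "many-to-one"
    return "many-to-many"


def relationship_table(ogs: Sequence[OrthoGroup], species_pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for og in ogs:
        row: dict[str, object] = {"og_id": og.og_id}
        for pair in species_pairs:
            row[f"{pair[0]}_vs_{pair[1]}"] = classify_relationship(og, pair)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Annotation transfer
# ---------------------------------------------------------------------------


def is_uncharacterized(description: str | None) -> bool:
    """True for absent/blank annotations and the database boilerplate labels."""
    if not description or not description.strip():
        return True
    low = description.lower()
    return any(marker in low for marker in _UNCHARACTERIZED_MARKERS)


def transfer_annotation(
    target_genes: Sequence[str],
    forward_hits: Iterable[HitRecord],
    reference_annotations: Mapping[str, tuple[str, str]],
    original_annotations: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Annotate each target gene from its top reference hit.

    ``reference_annotations`` maps reference gene -> (description,
    functional_group).  The summary reports how many target genes' ORIGINAL
    annotations were uncharacterized vs characterized, with the percentage to
    one decimal (half away from zero).  A target with no hits is annotated
    "no transfer" and counted as uncharacterized (it stays in the
    denominator).
    """
    ranked = rank_hits_per_query(forward_hits)
    rows = []
    for t in target_genes:
        hits = ranked.get(t, [])
        if hits:
            top = hits[0].subject_id
            desc, group = reference_annotations.get(top, ("", ""))
            rows.append({"gene_id": t, "top_reference_hit": top,
                         "transferred_description": desc, "functional_group": group,
                         "evalue": hits[0].evalue})
        else:
            rows.append({"gene_id": t, "top_reference_hit": None,
                         "transferred_description": "no transfer", "functional_group": None,
                         "evalue": math.nan})
    table = pd.DataFrame(rows)
    total = len(target_genes)
    if total == 0:
        return table, {"total": 0, "uncharacterized": 0, "characterized": 0,
                       "uncharacterized_pct": None, "characterized_pct": None}
    originals = original_annotations or {}
    # a gene with no transferable hit stays in the denominator and counts
    # as uncharacterized whatever its original label said
    unchar = sum(1 for t in target_genes
                 if t not in ranked or is_uncharacterized(originals.get(t)))
    summary = {
        "total": total,
        "uncharacterized": unchar,
        "characterized": total - unchar,
        "uncharacterized_pct": round_half_away(100.0 * unchar / total, 1),
        "characterized_pct": round_half_away(100.0 * (total - unchar) / total, 1),
    }
    return table, summary


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def copies_per_reference(ogs: Sequence[OrthoGroup], species: str,
                         n_reference_genes: int) -> float:
    """Mean ortholog copies of ``species`` per reference flowering gene
    (total members across OGs / reference gene count, 2 decimals)."""
    if n_reference_genes <= 0:
        raise ValueError("number of reference genes must be > 0")
    total = sum(og.count(species) for og in ogs)
    return round_half_away(total / n_reference_genes, 2)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    orthogroups: list[OrthoGroup]
    retained: dict[str, set[str]]          # reference gene -> retained targets
    forward_hits: dict[str, list[HitRecord]]  # per target species
    reverse_hits: list[HitRecord]
    graph: SimilarityGraph
    partition: list[set[str]]
    species_of: dict[str, str]
    reference_species: str

    def membership_table(self) -> pd.DataFrame:
        rows = [
            {"og_id": og.og_id, "species": sp, "gene_id": g}
            for og in self.orthogroups
            for sp, ids in sorted(og.members.items())
            for g in ids
        ]
        return pd.DataFrame(rows, columns=["og_id", "species", "gene_id"])


class _PairScorer:
    """Symmetric pairwise score/alignment cache over a fixed sequence set.

    The Smith-Waterman score and the local-alignment column statistics are
    symmetric in the pair, so each unordered pair is computed at most once no
    matter how many search directions request it.  E-values stay directional
    (they depend on query length and database size).
    """

    def __init__(self, records: Sequence[SequenceRecord], scheme: ScoringScheme):
        self.scheme = scheme
        self.records = {r.id: r for r in records}
        self._encoded = {r.id: scheme.encode(r.residues) for r in records}
        self._sub = scheme.matrix_array()
        self._scores: dict[tuple[str, str], int] = {}
        self._stats: dict[tuple[str, str], alignment.AlignmentResult] = {}

    def score(self, a: str, b: str) -> int:
        key = (a, b) if a <= b else (b, a)
        s = self._scores.get(key)
        if s is None:
            s = int(alignment._sw_score_kernel(
                self._encoded[key[0]], self._encoded[key[1]], self._sub,
                self.scheme.gap_open, self.scheme.gap_extend))
            self._scores[key] = s
        return s

    def stats(self, a: str, b: str) -> alignment.AlignmentResult:
        """Local-alignment statistics (identity, length, ...), pair-symmetric."""
        key = (a, b) if a <= b else (b, a)
        res = self._stats.get(key)
        if res is None:
            res = alignment.local_align(self.records[key[0]], self.records[key[1]], self.scheme)
            self._stats[key] = res
        return res

    def hit(self, query: str, subject: str, n_db: int,
            evalue_max: float | None = None) -> HitRecord | None:
        """Directional hit record, or None for a nonpositive score or an
        E-value at/above ``evalue_max``.  The E-value test happens before the
        (relatively expensive) alignment traceback."""
        score = self.score(query, subject)
        if score <= 0:
            return None
        E = alignment.evalue(score, len(self.records[query]), n_db, self.scheme)
        if evalue_max is not None and E >= evalue_max:
            return None
        res = self.stats(query, subject)
        flip = not (query <= subject)
        q_iv = res.subject_interval if flip else res.query_interval
        s_iv = res.query_interval if flip else res.subject_interval
        return HitRecord(
            query_id=query, subject_id=subject,
            percent_identity=res.percent_identity,
            alignment_length=res.alignment_length,
            mismatches=res.mismatches, gap_opens=res.gap_opens,
            q_start=q_iv[0], q_end=q_iv[1], s_start=s_iv[0], s_end=s_iv[1],
            evalue=E, bit_score=alignment.bit_score(score, self.scheme),
        )


def build_scorer(
    reference: Sequence[ReferenceGene],
    targets: Mapping[str, Sequence[SequenceRecord]],
    scheme: ScoringScheme | None = None,
) -> _PairScorer:
    """A reusable pairwise score/alignment cache over reference + targets.

    Pass it to several :func:`run_pipeline` calls (e.g. the candidate-scope
    run and the whole-proteome robustness check) so that no unordered pair is
    aligned twice."""
    scheme = scheme or ScoringScheme.protein_default()
    records = [g.protein for g in reference if g.is_protein_coding]
    for recs in targets.values():
        records.extend(recs)
    return _PairScorer(records, scheme)


def run_pipeline(
    reference: Sequence[ReferenceGene],
    targets: Mapping[str, Sequence[SequenceRecord]],
    reference_species: str = "AT",
    k: int = 3,
    evalue_max: float = 1e-5,
    min_match_pct: float = 50.0,
    params: ClusteringParams | None = None,
    scheme: ScoringScheme | None = None,
    cluster_scope: str = "candidates",
    scorer: _PairScorer | None = None,
) -> PipelineResult:
    """Run the full ortholog-prediction procedure.

    ``cluster_scope`` selects which proteins enter the clustering stage:
    ``"candidates"`` (reference + reciprocal-screen survivors — the primary
    protocol) or ``"all"`` (reference + entire target proteomes — the
    robustness check; OGs without reference genes are dropped either way).
    A ``scorer`` built by :func:`build_scorer` may be passed to share the
    pairwise-score cache across several runs on the same sequences.
    """
    if cluster_scope not in ("candidates", "all"):
        raise ValueError("cluster_scope must be 'candidates' or 'all'")
    params = params or ClusteringParams()
    scheme = scorer.scheme if scorer is not None else (scheme or ScoringScheme.protein_default())

    coding = [g for g in reference if g.is_protein_coding]
    ref_records = [g.protein for g in coding]
    ref_ids = [g.gene_id for g in coding]
    species_of: dict[str, str] = {g.gene_id: reference_species for g in coding}
    all_records = list(ref_records)
    for sp, recs in targets.items():
        for r in recs:
            if r.id in species_of:
                raise ValueError(f"gene id {r.id!r} appears in more than one species")
            species_of[r.id] = sp
            all_records.append(r)

    if scorer is None:
        scorer = _PairScorer(all_records, scheme)
    n_ref_residues = sum(len(r) for r in ref_records)

    # Round 1: reference -> each target proteome.
    forward: dict[str, list[HitRecord]] = {}
    candidates_by_species: dict[str, set[str]] = {}
    for sp, recs in targets.items():
        n_db = sum(len(r) for r in recs)
        hits = []
        for rid in ref_ids:
            for rec in recs:
                h = scorer.hit(rid, rec.id, n_db, evalue_max)
                if h is not None:
                    hits.append(h)
        forward[sp] = hits
        candidates_by_species[sp] = {h.subject_id for h in hits}

    # Round 2: unique forward hits -> reference proteome.
    reverse: list[HitRecord] = []
    for sp, cand in candidates_by_species.items():
        for t in sorted(cand):
            for rid in ref_ids:
                h = scorer.hit(t, rid, n_ref_residues, evalue_max)
                if h is not None:
                    reverse.append(h)

    all_forward = [h for hs in forward.values() for h in hs]
    retained = reciprocal_filter(all_forward, reverse, k=k)
    retained_targets = sorted(set().union(*retained.values())) if retained else []

    # Clustering set.
    if cluster_scope == "candidates":
        cluster_ids = list(ref_ids) + retained_targets
    else:
        cluster_ids = list(ref_ids) + [r.id for sp in targets for r in targets[sp]]
    cluster_set = sorted(set(cluster_ids))
    n_cluster_residues = sum(len(scorer.records[i]) for i in cluster_set)
    lengths = {i: len(scorer.records[i]) for i in cluster_set}

    ava_hits: list[HitRecord] = []
    for idx, q in enumerate(cluster_set):
        for s in cluster_set[idx + 1:]:
            score = scorer.score(q, s)
            if score <= 0:
                continue
            # test the pair at the more permissive (shorter-query) direction
            if alignment.evalue(score, min(lengths[q], lengths[s]),
                                n_cluster_residues, scheme) >= evalue_max:
                continue
            for h in (scorer.hit(q, s, n_cluster_residues, evalue_max),
                      scorer.hit(s, q, n_cluster_residues, evalue_max)):
                if h is not None:
                    ava_hits.append(h)

    graph = build_graph(
        ava_hits, lengths, {i: species_of[i] for i in cluster_set},
        params=params, evalue_max=evalue_max, min_match_pct=min_match_pct,
    )
    partition = mcl_cluster(graph, params)
    ogs = assign_orthogroups(partition, ref_ids, species_of)
    return PipelineResult(
        orthogroups=ogs, retained=retained, forward_hits=forward,
        reverse_hits=reverse, graph=graph, partition=partition,
        species_of=species_of, reference_species=reference_species,
    )


# ---------------------------------------------------------------------------
# Recovery scoring against a planted truth
# ---------------------------------------------------------------------------


def score_recovery(
    ogs: Sequence[OrthoGroup],
    truth_pairs: Iterable[tuple[str, str]],
    reference_species: str,
    decoy_ids: Iterable[str] = (),
) -> dict[str, float | int]:
    """Precision/recall of planted (reference, target) co-membership pairs.

    A planted pair is recovered when both genes share an OG.  Predicted pairs
    are all reference x non-reference co-memberships.  Also reports how many
    decoys infiltrated any OG.
    """
    truth = set(truth_pairs)
    predicted: set[tuple[str, str]] = set()
    member_set: set[str] = set()
    for og in ogs:
        refs = og.members.get(reference_species, [])
        others = [g for sp, ids in og.members.items() if sp != reference_species for g in ids]
        member_set.update(og.all_members)
        for r in refs:
            for t in others:
                predicted.add((r, t))
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    decoys_in = len(member_set & set(decoy_ids))
    return {
        "precision": precision,
        "recall": recall,
        "true_positive_pairs": tp,
        "predicted_pairs": len(predicted),
        "planted_pairs": len(truth),
        "decoys_in_orthogroups": decoys_in,
    }
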