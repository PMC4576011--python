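"""Structural, positional, domain and similarity characterization of
predicted flowering genes.

Covers: per-species gene-structure summaries (transcripts, gene length,
exon/intron sizes, protein length), OG-level intron-size comparison,
chromosome x functional-group distributions with deterministic random
placement of position-less genes, longest-isoform selection, shared InterPro
domains per orthogroup, and per-pathway protein-similarity summaries.

Conventions: interval lengths are 1-based inclusive (bp); single-exon genes
never contribute intron values; percentages are rounded half away from zero
(one decimal where reports print decimals, integers elsewhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import ScoringScheme, percent_similarity_global
from .core_io import DomainAnnotation, GeneModel, SequenceRecord
from .orthology import FUNCTIONAL_GROUPS, OrthoGroup, round_half_away

logger = logging.getLogger(__name__)

STRUCTURE_METRICS = (
    "transcripts_per_gene",
    "gene_length_bp",
    "exons_per_gene",
    "exon_size_bp",
    "intron_size_bp",
    "protein_length_aa",
)


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("metric summary must satisfy min <= mean <= max")


@dataclass
class StructureSummary:
    """Table of (mean, min, max) per structural metric for one species.

    ``intron_size_bp`` is ``None`` when no multi-exon gene exists (intron
    statistics are only ever computed over multi-exon genes)."""

    species: str
    n_genes: int
    metrics: dict[str, MetricSummary | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in STRUCTURE_METRICS:
            m = self.metrics.get(name)
            rows.append({
                "metric": name,
                "mean": None if m is None else m.mean,
                "min": None if m is None else m.min,
                "max": None if m is None else m.max,
            })
        return pd.DataFrame(rows)


def _summary(values: Sequence[float]) -> MetricSummary | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return MetricSummary(mean=float(arr.mean()), min=float(arr.min()), max=float(arr.max()))


def structure_summary(
    gene_models: Sequence[GeneModel],
    proteins: Mapping[str, SequenceRecord] | None,
    species: str,
) -> StructureSummary:
    """Six-metric structure summary for one species.

    Exon counts and exon/intron sizes are pooled over *all* transcripts of
    all genes; intron sizes only over transcripts with >= 2 exons
    (single-exon genes are excluded from intron sizing, not from anything
    else).  Protein lengths come from the supplied per-gene (longest-isoform)
    protein map; genes without a mapped protein are skipped for that metric
    only.
    """
    transcripts_per_gene: list[float] = []
    gene_lengths: list[float] = []
    exons_per_transcript: list[float] = []
    exon_sizes: list[float] = []
    intron_sizes: list[float] = []
    protein_lengths: list[float] = []
    for g in gene_models:
        transcripts_per_gene.append(len(g.transcripts))
        gene_lengths.append(g.length)
        for t in g.transcripts:
            if not t.exons:
                raise ValueError(f"gene {g.gene_id!r}: transcript with zero exons")
            exons_per_transcript.append(len(t.exons))
            exon_sizes.extend(t.exon_lengths)
            if len(t.exons) >= 2:
                intron_sizes.extend(t.intron_lengths)
        if proteins is not None and g.gene_id in proteins:
            protein_lengths.append(len(proteins[g.gene_id]))
    return StructureSummary(
        species=species,
        n_genes=len(gene_models),
        metrics={
            "transcripts_per_gene": _summary(transcripts_per_gene),
            "gene_length_bp": _summary(gene_lengths),
            "exons_per_gene": _summary(exons_per_transcript),
            "exon_size_bp": _summary(exon_sizes),
            "intron_size_bp": _summary(intron_sizes),
            "protein_length_aa": _summary(protein_lengths),
        },
    )


def og_intron_comparison(
    og: OrthoGroup,
    gene_models: Mapping[str, GeneModel],
) -> dict[str, object]:
    """Mean intron length per species within one orthogroup.

    Species whose members are all single-exon report ``None``; an OG whose
    members are single-exon in every species is flagged intronless.
    """
    if not og.all_members:
        raise ValueError("empty orthogroup")
    per_species: dict[str, float | None] = {}
    for sp, members in sorted(og.members.items()):
        introns: list[int] = []
        for gid in members:
            model = gene_models.get(gid)
            if model is None:
                continue
            for t in model.transcripts:
                if len(t.exons) >= 2:
                    introns.extend(t.intron_lengths)
        per_species[sp] = float(np.mean(introns)) if introns else None
    return {
        "og_id": og.og_id,
        "per_species": per_species,
        "intronless": all(v is None for v in per_species.values()),
    }


# ---------------------------------------------------------------------------
# Chromosome distributions
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeDistribution:
    """Counts per chromosome x functional group, plus deterministic random
    coordinates for genes with a known chromosome but unknown position."""

    species: str
    counts: pd.DataFrame                  # index chromosome, columns functional group
    coordinates: pd.DataFrame             # gene_id, chromosome, position, approximate
    n_unplaced: int
    placement_seed: int

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum()) + self.n_unplaced


def chromosome_distribution(
    genes: pd.DataFrame,
    chromosome_lengths: Mapping[str, int],
    seed: int,
    species: str = "unknown",
) -> ChromosomeDistribution:
    """Chromosome x functional-group counts with seeded placement.

    ``genes`` needs columns ``gene_id``, ``functional_group``, ``chromosome``
    (nullable) and ``position`` (nullable).  A gene with an unknown
    chromosome name counts as unplaced.  Genes with a chromosome but no
    position get a uniform-random coordinate on that chromosome under the
    stated seed and are flagged approximate; placement never changes counts.
    """
    rng = np.random.default_rng(seed)
    known = set(chromosome_lengths)
    rows = []
    count_index: dict[tuple[str, str], int] = {}
    n_unplaced = 0
    for rec in genes.itertuples():
        chrom = getattr(rec, "chromosome", None)
        if chrom is None or (isinstance(chrom, float) and np.isnan(chrom)) or chrom not in known:
            n_unplaced += 1
            continue
        group = rec.functional_group
        count_index[(chrom, group)] = count_index.get((chrom, group), 0) + 1
        pos = getattr(rec, "position", None)
        approximate = pos is None or (isinstance(pos, float) and np.isnan(pos))
        if approximate:
            pos = int(rng.integers(1, chromosome_lengths[chrom] + 1))
        rows.append({"gene_id": rec.gene_id, "chromosome": chrom,
                     "position": int(pos), "approximate": approximate})
    chroms = sorted(known)
    groups = list(FUNCTIONAL_GROUPS)
    counts = pd.DataFrame(0, index=chroms, columns=groups, dtype=int)
    for (chrom, group), n in count_index.items():
        if group not in counts.columns:
            counts[group] = 0
        counts.loc[chrom, group] = n
    coords = pd.DataFrame(rows, columns=["gene_id", "chromosome", "position", "approximate"])
    return ChromosomeDistribution(species=species, counts=counts, coordinates=coords,
                                  n_unplaced=n_unplaced, placement_seed=seed)


def placement_rate(genes: pd.DataFrame) -> int:
    """Percent of genes with chromosome positions, rounded to an integer."""
    if len(genes) == 0:
        raise ValueError("placement rate undefined for zero genes")

    def _has(v) -> bool:
        return v is not None and not (isinstance(v, float) and np.isnan(v))

    positioned = sum(
        1 for rec in genes.itertuples()
        if _has(getattr(rec, "chromosome", None)) and _has(getattr(rec, "position", None))
    )
    return int(round_half_away(100.0 * positioned / len(genes), 0))


# ---------------------------------------------------------------------------
# Isoforms and domains
# ---------------------------------------------------------------------------


def longest_isoform(
    gene_proteins: Mapping[str, Sequence[SequenceRecord]],
) -> dict[str, SequenceRecord]:
    """One protein per gene: the longest isoform; ties break to the
    lexicographically smallest isoform id (deterministic)."""
    out: dict[str, SequenceRecord] = {}
    for gene, isoforms in gene_proteins.items():
        if not isoforms:
            raise ValueError(f"gene {gene!r} has no protein isoforms")
        out[gene] = min(isoforms, key=lambda r: (-len(r), r.id))
    return out


def _domains_of(protein_id: str, domains_by_protein: Mapping[str, Iterable[str]]) -> set[str]:
    return set(domains_by_protein.get(protein_id, ()))


def shared_domains(
    og: OrthoGroup,
    domains_by_protein: Mapping[str, Iterable[str]],
    id_map: Mapping[str, str] | None = None,
    scope: str = "all-species",
) -> set[str]:
    """InterPro domains shared across an orthogroup.

    Under the default ``all-species`` scope a domain counts as shared iff it
    occurs in >= 1 member of *every* species represented in the OG.
    ``any-pair`` relaxes this to any two members of different species.
    ``id_map`` translates gene ids to (longest-isoform) protein ids when they
    differ.
    """
    if scope not in ("all-species", "any-pair"):
        raise ValueError("scope must be 'all-species' or 'any-pair'")
    id_map = id_map or {}
    per_species: list[set[str]] = []
    for sp, members in sorted(og.members.items()):
        union: set[str] = set()
        for gid in members:
            union |= _domains_of(id_map.get(gid, gid), domains_by_protein)
        per_species.append(union)
    if not per_species:
        return set()
    if scope == "all-species":
        shared = per_species[0].copy()
        for s in per_species[1:]:
            shared &= s
        return shared
    out: set[str] = set()
    for i, a in enumerate(per_species):
        for b in per_species[i + 1:]:
            out |= a & b
    return out


def domain_sharing_summary(
    ogs: Sequence[OrthoGroup],
    domains_by_protein: Mapping[str, Iterable[str]],
    reference_species: str = "AT",
    id_map: Mapping[str, str] | None = None,
    scope: str = "all-species",
) -> tuple[int, int, int | None]:
    """(eligible OGs, sharing OGs, integer-rounded sharing %).

    Eligible OGs are those with at least one non-reference member (OGs with
    no target-species orthologs are excluded from the rate).  Returns ``None``
    for the percentage when nothing is eligible.
    """
    eligible = [og for og in ogs
                if any(sp != reference_species and ids for sp, ids in og.members.items())]
    sharing = sum(1 for og in eligible
                  if shared_domains(og, domains_by_protein, id_map=id_map, scope=scope))
    if not eligible:
        logger.warning("no orthogroup has target-species members; sharing rate undefined")
        return 0, 0, None
    pct = int(round_half_away(100.0 * sharing / len(eligible), 0))
    return len(eligible), sharing, pct


# ---------------------------------------------------------------------------
# Per-pathway similarity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSimilaritySummary:
    functional_group: str
    species_pair: tuple[str, str]
    mean_similarity: float
    sd_similarity: float | None     # sample SD (n-1); None for a single pair
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0 <= self.mean_similarity <= 100:
            raise ValueError("mean similarity must lie in [0, 100]")
        if self.sd_similarity is not None and self.sd_similarity < 0:
            raise ValueError("similarity SD must be >= 0")


def group_similarity(
    ogs: Sequence[OrthoGroup],
    proteins: Mapping[str, SequenceRecord],
    reference_groups: Mapping[str, str],
    reference_species: str = "AT",
    scheme: ScoringScheme | None = None,
    species_pairs: Sequence[tuple[str, str]] | None = None,
) -> list[GroupSimilaritySummary]:
    """Mean/SD of global-alignment protein similarity per functional group
    and species pair.

    The pair population for a (group, species pair) is every cross-species
    member pair within OGs whose reference member(s) belong to the group (an
    OG whose reference members span several groups contributes its pairs to
    each).  Similarity is the positive-substitution column fraction of the
    global alignment; SD is the sample SD (n-1).  Genes without a protein in
    ``proteins`` are skipped.
    """
    scheme = scheme or ScoringScheme.protein_default()
    if species_pairs is None:
        all_species = sorted({sp for og in ogs for sp in og.members})
        species_pairs = [(a, b) for i, a in enumerate(all_species)
                         for b in all_species[i + 1:]]
    sims: dict[tuple[str, tuple[str, str]], list[float]] = {}
    cache: dict[tuple[str, str], float] = {}

    def _sim(a: str, b: str) -> float | None:
        if a not in proteins or b not in proteins:
            return None
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = percent_similarity_global(proteins[key[0]], proteins[key[1]], scheme)
        return cache[key]

    for og in ogs:
        groups = sorted({reference_groups[g] for g in og.members.get(reference_species, [])
                         if g in reference_groups})
        if not groups:
            continue
        for pair in species_pairs:
            a_members = og.members.get(pair[0], [])
            b_members = og.members.get(pair[1], [])
            for a in a_members:
                for b in b_members:
                    s = _sim(a, b)
                    if s is None:
                        continue
                    for grp in groups:
                        sims.setdefault((grp, pair), []).append(s)

    out = []
    for (grp, pair), values in sorted(sims.items()):
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
        out.append(GroupSimilaritySummary(
            functional_group=grp, species_pair=pair,
            mean_similarity=float(arr.mean()), sd_similarity=sd, n_pairs=len(arr),
        ))
    return out


def group_similarity_table(summaries: Sequence[GroupSimilaritySummary]) -> pd.DataFrame:
    rows = [
        {
            "functional_group": s.functional_group,
            "species_pair": f"{s.species_pair[0]} vs {s.species_pair[1]}",
            "mean_similarity": round_half_away(s.mean_similarity, 2),
            "sd_similarity": None if s.sd_similarity is None else round_half_away(s.sd_similarity, 2),
            "n_pairs": s.n_pairs,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
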