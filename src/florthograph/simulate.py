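"""Truth-tagged synthetic inputs for the whole pipeline.

The generator emulates the comparative design the package analyzes: a
reference flowering-gene set (about two hundred genes split over seven
functional groups and five chromosomes, with a handful of microRNA entries
that carry no protein), a hexaploid-like target whose ortholog copies sit on
homologous chromosomes of the A/B/D subgenomes, a diploid-like target with
0-2 copies per reference gene, unrelated decoy proteins, species-specific
intron-length scales (cereal introns larger than the reference's),
conserved InterPro-style domain content within ortholog families, and
matched-tissue log2 expression (13 shared tissues x 3 replicates, plus two
extra developing-caryopsis samples in the diploid) with a tunable
ortholog-profile correlation and silenced ("virtually unexpressed")
pseudogene paralogs.

Everything is deterministic under the mandatory seed, and every non-decoy
target gene is recorded in exactly one family of the truth table, so planted
orthology, domain content, probe mapping and profile correlations are all
known quantities a test can score against.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .core_io import (
    DomainAnnotation,
    ExpressionMatrix,
    GeneModel,
    SequenceRecord,
    Transcript,
    write_expression,
    write_fasta,
    write_gff3,
    write_interpro_tsv,
)
from .orthology import FUNCTIONAL_GROUPS, ReferenceGene

# Amino-acid background frequencies (approximate vertebrate/plant averages);
# decoys and reference proteins are both drawn from this distribution.
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array([
    0.083, 0.014, 0.054, 0.062, 0.039, 0.072, 0.022, 0.052, 0.058, 0.090,
    0.024, 0.044, 0.050, 0.040, 0.051, 0.069, 0.058, 0.066, 0.013, 0.032,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

#: The 13 tissues shared by the two cereal expression designs.
SHARED_TISSUES = (
    "germinating seed coleoptile",
    "germinating seed root",
    "germinating seed embryo",
    "seedling root",
    "seedling crown",
    "seedling leaf",
    "immature inflorescence",
    "floral bracts before anthesis",
    "pistils before anthesis",
    "anthers before anthesis",
    "3-5 DAP caryopsis",
    "22 DAP embryo",
    "22 DAP endosperm",
)

#: Extra samples present only in the diploid's design.
EXTRA_DIPLOID_TISSUES = ("10 DAP caryopsis", "16 DAP caryopsis")

# Functional-group proportions of the reference compilation (7:41:19:7:32:69:15).
_GROUP_WEIGHTS = {
    "autonomous": 7,
    "flower development": 41,
    "gibberellin": 19,
    "pathway integration": 7,
    "photoperiod": 32,
    "regulation": 69,
    "vernalization": 15,
}

# Per-chromosome weights of the reference compilation (protein-coding rows).
_CHROMOSOME_WEIGHTS = (48, 33, 32, 25, 52)


def _default_group_proportions() -> dict[str, float]:
    total = sum(_GROUP_WEIGHTS.values())
    return {g: w / total for g, w in _GROUP_WEIGHTS.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study, with the comparative design as defaults.

    ``target_identity`` is the mean fractional protein identity of planted
    orthologs vs their reference gene; ``group_identity_offsets`` shift it
    per functional group (vernalization least conserved by default).
    ``intron_scale`` is the per-species mean intron length in bp.  The seed
    is mandatory: all outputs are byte-deterministic under it.
    """

    seed: int
    n_reference_genes: int = 200
    n_microrna: int = 14
    functional_group_proportions: Mapping[str, float] = field(
        default_factory=_default_group_proportions)
    n_reference_chromosomes: int = 5
    diploid_copy_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.55, 2: 0.40})
    hexaploid_homoeolog_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.25, 2: 0.30, 3: 0.40})
    target_identity: float = 0.70
    group_identity_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"vernalization": -0.10, "autonomous": -0.03,
                                 "pathway integration": 0.03})
    n_decoys: int = 40
    pseudogene_fraction: float = 0.10
    protein_length_mean: float = 529.0
    protein_length_sigma: float = 0.35
    intron_scale: Mapping[str, float] = field(
        default_factory=lambda: {"reference": 468.0, "hexaploid": 924.0, "diploid": 856.0})
    exon_size_mean: float = 466.0
    placed_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"reference": 1.0, "hexaploid": 0.58, "diploid": 0.97})
    transcripts_mean: Mapping[str, float] = field(
        default_factory=lambda: {"reference": 1.4, "hexaploid": 1.0, "diploid": 2.8})
    n_tissues: int = 13
    n_replicates: int = 3
    profile_correlation: float = 0.8
    noise_sd: float = 0.5
    profile_sd: float = 2.0
    profile_baseline: float = 8.0
    uncharacterized_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"hexaploid": 0.962, "diploid": 0.931})
    reference_species: str = "AT"
    species_labels: Mapping[str, str] = field(
        default_factory=lambda: {"hexaploid": "TA", "diploid": "HV"})

    def __post_init__(self) -> None:
        props = self.functional_group_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("functional group proportions must sum to 1")
        if set(props) - set(FUNCTIONAL_GROUPS):
            raise ValueError("unknown functional group in proportions")
        if not 0 < self.target_identity <= 1:
            raise ValueError("target_identity must lie in (0, 1]")
        for dist_name in ("diploid_copy_distribution", "hexaploid_homoeolog_distribution"):
            dist = getattr(self, dist_name)
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{dist_name} must sum to 1")


# ---------------------------------------------------------------------------
# Sequence-level machinery
# ---------------------------------------------------------------------------


_B62 = substitution_matrices.load("BLOSUM62")
_POSITIVE_PARTNERS = {
    a: [b for b in _AA if b != a and _B62[a, b] > 0] for a in _AA
}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length, p=_AA_FREQ))


def _draw_length(rng: np.random.Generator, mean: float, sigma: float, minimum: int = 60) -> int:
    mu = math.log(mean) - sigma**2 / 2.0
    return max(minimum, int(rng.lognormal(mu, sigma)))


def mutate_protein(rng: np.random.Generator, residues: str, identity: float) -> str:
    """Mutate a protein to roughly the requested fractional identity.

    Substitutions are biased toward BLOSUM62-positive (conservative)
    partners; up to two short indels (total <= 2% of length) consume part of
    the divergence budget.  The realized global-alignment identity lands
    within a few points of the request.
    """
    seq = list(residues)
    L = len(seq)
    budget = int(round((1.0 - identity) * L))
    # Small indels first.
    indel_total = 0
    n_indels = int(min(rng.poisson(1.0), 2))
    max_indel = max(0, int(0.02 * L))
    for _ in range(n_indels):
        if indel_total >= max_indel or budget - indel_total <= 0:
            break
        size = int(min(1 + rng.geometric(0.5), max_indel - indel_total,
                       budget - indel_total))
        if size <= 0:
            break
        indel_total += size
        if rng.random() < 0.5 and len(seq) > size + 10:  # deletion
            pos = int(rng.integers(0, len(seq) - size))
            del seq[pos:pos + size]
        else:  # insertion
            pos = int(rng.integers(0, len(seq)))
            seq[pos:pos] = list(_random_protein(rng, size))
    n_sub = max(0, budget - indel_total)
    positions = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for pos in positions:
        orig = seq[pos]
        partners = _POSITIVE_PARTNERS.get(orig, [])
        if partners and rng.random() < 0.7:
            seq[pos] = partners[int(rng.integers(0, len(partners)))]
        else:
            alternatives = [a for a in _AA if a != orig]
            seq[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(seq)


def _make_gene_model(rng: np.random.Generator, gene_id: str, species_key: str,
                     chromosome: str | None, config: SimulationConfig,
                     protein_len: int) -> GeneModel:
    """Exon/intron structure with the species' intron-length scale.

    About 8% of genes are single-exon; the rest have 2 + Poisson exons.
    Extra transcripts (per the species' alternative-splicing propensity)
    reuse the exon chain, dropping one internal exon when possible.
    """
    if rng.random() < 0.08:
        n_exons = 1
    else:
        n_exons = 2 + int(rng.poisson(4.0))
    exon_sigma = 0.6
    mu_e = math.log(config.exon_size_mean) - exon_sigma**2 / 2
    exon_lens = [max(40, int(rng.lognormal(mu_e, exon_sigma))) for _ in range(n_exons)]
    intron_mean = float(config.intron_scale[species_key])
    intron_sigma = 0.7
    mu_i = math.log(intron_mean) - intron_sigma**2 / 2
    intron_lens = [max(40, int(rng.lognormal(mu_i, intron_sigma)))
                   for _ in range(max(0, n_exons - 1))]
    start = int(rng.integers(1, 30_000_000))
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    transcripts = [Transcript(transcript_id=f"{gene_id}.1", exons=tuple(exons),
                              protein_length=protein_len)]
    extra = int(rng.poisson(max(0.0, config.transcripts_mean[species_key] - 1.0)))
    for j in range(extra):
        if len(exons) >= 3:
            drop = int(rng.integers(1, len(exons) - 1))
            alt = tuple(e for idx, e in enumerate(exons) if idx != drop)
        else:
            alt = tuple(exons)
        transcripts.append(Transcript(transcript_id=f"{gene_id}.{j + 2}", exons=alt,
                                      protein_length=protein_len))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id=gene_id, species=species_key, transcripts=tuple(transcripts),
                     chromosome=chromosome, strand=strand)


# ---------------------------------------------------------------------------
# Reference set
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReference:
    genes: list[ReferenceGene]             # protein-coding entries, with proteins
    microrna_ids: list[str]
    gene_models: list[GeneModel]
    metadata: pd.DataFrame                 # all entries incl. microRNA rows


def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> SimulatedReference:
    """Reference flowering-gene compilation: proteins, pathway labels,
    chromosomes, gene models, plus protein-less microRNA rows."""
    rng = rng or np.random.default_rng(config.seed)
    groups = list(FUNCTIONAL_GROUPS)
    probs = np.array([config.functional_group_proportions.get(g, 0.0) for g in groups])
    chrom_names = [f"{config.reference_species}{i+1}"
                   for i in range(config.n_reference_chromosomes)]
    cw = np.array(_CHROMOSOME_WEIGHTS[:config.n_reference_chromosomes], dtype=float)
    cw = cw / cw.sum()

    genes: list[ReferenceGene] = []
    models: list[GeneModel] = []
    meta_rows = []
    for i in range(config.n_reference_genes):
        gid = f"{config.reference_species}G{i+1:04d}"
        group = groups[int(rng.choice(len(groups), p=probs))]
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=cw))]
        plen = _draw_length(rng, config.protein_length_mean, config.protein_length_sigma)
        protein = SequenceRecord(id=gid, residues=_random_protein(rng, plen),
                                 description=f"flowering protein ({group})",
                                 alphabet="protein")
        model = _make_gene_model(rng, gid, "reference", chrom, config, plen)
        genes.append(ReferenceGene(gene_id=gid, functional_group=group, chromosome=chrom,
                                   protein=protein, is_protein_coding=True,
                                   description=protein.description))
        models.append(model)
        meta_rows.append({"gene_id": gid, "functional_group": group, "chromosome": chrom,
                          "is_protein_coding": True, "position": model.start})
    microrna_ids = []
    for i in range(config.n_microrna):
        gid = f"{config.reference_species}MIR{i+1:03d}"
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=cw))]
        microrna_ids.append(gid)
        meta_rows.append({"gene_id": gid, "functional_group": "microRNA", "chromosome": chrom,
                          "is_protein_coding": False, "position": int(rng.integers(1, 30_000_000))})
    return SimulatedReference(genes=genes, microrna_ids=microrna_ids, gene_models=models,
                              metadata=pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# Target species
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSpecies:
    species_key: str                      # "hexaploid" | "diploid"
    label: str                            # species tag used in gene ids
    sequences: list[SequenceRecord]       # orthologs + decoys
    gene_models: list[GeneModel]
    truth: pd.DataFrame                   # one row per planted ortholog copy
    decoy_ids: list[str]
    original_annotations: dict[str, str]
    placements: pd.DataFrame              # gene_id, chromosome, position (nullable)


def _copy_count(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    ks = sorted(dist)
    return int(rng.choice(ks, p=[dist[k] for k in ks]))


def simulate_target_species(
    reference: SimulatedReference,
    config: SimulationConfig,
    species_key: str,
    rng: np.random.Generator,
) -> SimulatedSpecies:
    """Planted ortholog copies, decoys, gene models and truth rows for one
    target species.

    Hexaploid copies of one reference gene go to the homologous chromosome
    group of distinct subgenomes (A/B/D); diploid copies sit on the matching
    "H" chromosome.  Protein identity per family is the configured target
    plus the functional-group offset, jittered slightly per copy.  A fraction
    of copies (never the first of a family) is flagged pseudogene — silenced
    later in the expression simulator but sequence-intact.
    """
    if species_key not in ("hexaploid", "diploid"):
        raise ValueError("species_key must be 'hexaploid' or 'diploid'")
    label = config.species_labels[species_key]
    hexaploid = species_key == "hexaploid"
    dist = (config.hexaploid_homoeolog_distribution if hexaploid
            else config.diploid_copy_distribution)
    placed_p = float(config.placed_fraction[species_key])

    sequences: list[SequenceRecord] = []
    models: list[GeneModel] = []
    truth_rows = []
    annotations: dict[str, str] = {}
    placements = []
    unchar_p = float(config.uncharacterized_fraction[species_key])

    for ref_gene in reference.genes:
        n_copies = _copy_count(rng, dist)
        if n_copies == 0:
            continue
        group_offset = float(config.group_identity_offsets.get(ref_gene.functional_group, 0.0))
        chrom_group = ref_gene.chromosome[-1] if ref_gene.chromosome else "1"
        subgenomes = list(rng.permutation(["A", "B", "D"]))[:n_copies] if hexaploid else None
        for c in range(n_copies):
            identity = min(0.99, max(0.35,
                           config.target_identity + group_offset + rng.normal(0, 0.02)))
            if hexaploid:
                sub = subgenomes[c]
                gid = f"{label}_{ref_gene.gene_id}_{sub}"
                chrom = f"{chrom_group}{sub}"
            else:
                sub = ""
                gid = f"{label}_{ref_gene.gene_id}_{c+1}"
                chrom = f"{chrom_group}H"
            residues = mutate_protein(rng, ref_gene.protein.residues, identity)
            # only duplicate copies can be silenced pseudogenes
            pseudo = bool(c > 0 and rng.random() < config.pseudogene_fraction)
            placed = bool(rng.random() < placed_p)
            model = _make_gene_model(rng, gid, species_key,
                                     chrom if placed else None, config, len(residues))
            sequences.append(SequenceRecord(id=gid, residues=residues, alphabet="protein"))
            models.append(model)
            annotations[gid] = ("uncharacterized protein" if rng.random() < unchar_p
                                else f"putative {ref_gene.functional_group} protein")
            placements.append({"gene_id": gid, "chromosome": chrom if placed else None,
                               "position": model.start if placed else None,
                               "functional_group": ref_gene.functional_group})
            truth_rows.append({
                "reference_id": ref_gene.gene_id, "target_id": gid, "species": label,
                "subgenome": sub, "identity": identity, "pseudogene": pseudo,
                "functional_group": ref_gene.functional_group,
            })

    decoy_ids = []
    for i in range(config.n_decoys):
        gid = f"{label}_DECOY{i+1:03d}"
        decoy_ids.append(gid)
        plen = _draw_length(rng, config.protein_length_mean, config.protein_length_sigma)
        sequences.append(SequenceRecord(id=gid, residues=_random_protein(rng, plen),
                                        alphabet="protein"))
        chrom_group = str(1 + int(rng.integers(0, config.n_reference_chromosomes)))
        chrom = f"{chrom_group}{'ABD'[int(rng.integers(0, 3))] if hexaploid else 'H'}"
        model = _make_gene_model(rng, gid, species_key, chrom, config, plen)
        models.append(model)
        annotations[gid] = "uncharacterized protein"
        placements.append({"gene_id": gid, "chromosome": chrom, "position": model.start,
                           "functional_group": None})

    truth = pd.DataFrame(truth_rows, columns=["reference_id", "target_id", "species",
                                              "subgenome", "identity", "pseudogene",
                                              "functional_group"])
    return SimulatedSpecies(species_key=species_key, label=label, sequences=sequences,
                            gene_models=models, truth=truth, decoy_ids=decoy_ids,
                            original_annotations=annotations,
                            placements=pd.DataFrame(placements))


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------


def simulate_domains(
    reference: SimulatedReference,
    species: Sequence[SimulatedSpecies],
    config: SimulationConfig,
    rng: np.random.Generator,
    p_retain: float = 0.95,
) -> tuple[list[DomainAnnotation], dict[str, list[str]]]:
    """Family-conserved synthetic InterPro domains.

    Each ortholog family (reference gene + its planted copies) receives 1-13
    synthetic IPR accessions (mostly one or two); every member carries each
    family domain independently with probability ``p_retain``, the reference
    member always.  Decoys receive accessions disjoint from every family.
    Returns the annotation rows and the per-family assigned domain sets.
    """
    annotations: list[DomainAnnotation] = []
    family_domains: dict[str, list[str]] = {}
    counter = 900000
    for ref_gene in reference.genes:
        n_domains = int(min(13, 1 + rng.poisson(0.8)))
        ids = []
        for _ in range(n_domains):
            counter += 1
            ids.append(f"IPR{counter:06d}")
        family_domains[ref_gene.gene_id] = ids
        members = [ref_gene.gene_id] + [
            row.target_id for sp in species for row in sp.truth.itertuples()
            if row.reference_id == ref_gene.gene_id
        ]
        for member in members:
            for j, ipr in enumerate(ids):
                if member != ref_gene.gene_id and rng.random() > p_retain:
                    continue
                start = 10 + 40 * j
                annotations.append(DomainAnnotation(
                    protein_id=member, start=start, end=start + 35,
                    interpro_id=ipr, description=f"synthetic family domain {ipr}"))
    for sp in species:
        for gid in sp.decoy_ids:
            counter += 1
            annotations.append(DomainAnnotation(
                protein_id=gid, start=10, end=45,
                interpro_id=f"IPR{counter:06d}",
                description="synthetic decoy domain"))
    return annotations, family_domains


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExpression:
    matrix: ExpressionMatrix              # probe-level, replicate columns
    probes: list[SequenceRecord]          # probe target sequences (nucleotide)
    probe_mapping: pd.DataFrame           # probe_id -> gene_id truth
    gene_nucleotides: list[SequenceRecord]


def _family_latents(reference: SimulatedReference, config: SimulationConfig,
                    rng: np.random.Generator, n_tissues: int) -> dict[str, np.ndarray]:
    return {g.gene_id: rng.normal(0.0, 1.0, size=n_tissues) for g in reference.genes}


def simulate_expression(
    reference: SimulatedReference,
    sp: SimulatedSpecies,
    config: SimulationConfig,
    rng: np.random.Generator,
    family_latents: Mapping[str, np.ndarray],
) -> SimulatedExpression:
    """Replicate-level log2 expression, probe targets and mapping truth.

    Each ortholog family shares a latent standardized tissue profile ``z``;
    a member's tissue-mean profile is
    ``baseline + profile_sd * (sqrt(r)*z + sqrt(1-r)*eps)`` so that two
    members of the same family correlate at ``r`` on tissue means.  ``r`` is
    the configured profile correlation inflated analytically to compensate
    for the replicate noise that the tissue averaging retains, so the
    *observed* tissue-mean correlation targets the configured value.
    Pseudogenes are silenced to a low constant.  The diploid design appends
    the two extra developing-caryopsis samples.  Probe targets are exact
    200-nt substrings of the (synthetic) gene transcripts, so the mapping
    truth is exact.
    """
    tissues = list(SHARED_TISSUES[:config.n_tissues])
    if sp.species_key == "diploid":
        tissues = tissues + list(EXTRA_DIPLOID_TISSUES)
    n_t = len(tissues)
    rho = config.profile_correlation
    # Analytic compensation: tissue means retain noise_sd^2 / n_replicates of
    # replicate variance, which dilutes the latent correlation.
    dilution = config.profile_sd**2 / (config.profile_sd**2
                                       + config.noise_sd**2 / config.n_replicates)
    r_latent = min(1.0, rho / dilution) if rho > 0 else 0.0

    rows = {}
    probe_rows = []
    probes: list[SequenceRecord] = []
    gene_nt: list[SequenceRecord] = []
    pseudo = dict(zip(sp.truth["target_id"], sp.truth["pseudogene"]))
    family_of = dict(zip(sp.truth["target_id"], sp.truth["reference_id"]))
    sample_cols = [(t, r + 1) for t in tissues for r in range(config.n_replicates)]

    for rec in sp.sequences:
        gid = rec.id
        if gid in family_of:
            z = family_latents[family_of[gid]]
            z_full = np.concatenate([z, rng.normal(0.0, 1.0, size=n_t - len(z))]) \
                if n_t > len(z) else z[:n_t]
            eps = rng.normal(0.0, 1.0, size=n_t)
            profile = (config.profile_baseline
                       + config.profile_sd * (math.sqrt(r_latent) * z_full
                                              + math.sqrt(max(0.0, 1 - r_latent)) * eps))
        else:  # decoy: independent profile
            profile = config.profile_baseline + config.profile_sd * rng.normal(0.0, 1.0, size=n_t)
        if pseudo.get(gid, False):
            profile = rng.normal(2.0, 0.2, size=n_t)  # virtually unexpressed
        reps = np.repeat(profile, config.n_replicates) + rng.normal(
            0.0, config.noise_sd, size=n_t * config.n_replicates)
        probe_id = f"{sp.label}_ps_{gid}"
        rows[probe_id] = reps
        # nucleotide transcript + exact probe substring
        nt = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1200)])
        start = int(rng.integers(0, 1000))
        gene_nt.append(SequenceRecord(id=gid, residues=nt, alphabet="nucleotide"))
        probes.append(SequenceRecord(id=probe_id, residues=nt[start:start + 200],
                                     alphabet="nucleotide"))
        probe_rows.append({"probe_id": probe_id, "gene_id": gid})

    sample_ids = [f"{sp.label}_{t.replace(' ', '_')}_r{r}" for t, r in sample_cols]
    values = pd.DataFrame(rows, index=sample_ids).T
    matrix = ExpressionMatrix(values=values, samples=sample_cols)
    return SimulatedExpression(matrix=matrix, probes=probes,
                               probe_mapping=pd.DataFrame(probe_rows),
                               gene_nucleotides=gene_nt)


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    reference: SimulatedReference
    hexaploid: SimulatedSpecies
    diploid: SimulatedSpecies
    domains: list[DomainAnnotation]
    family_domains: dict[str, list[str]]
    expression: dict[str, SimulatedExpression]   # keyed by species label

    @property
    def truth(self) -> pd.DataFrame:
        return pd.concat([self.hexaploid.truth, self.diploid.truth], ignore_index=True)

    def planted_pairs(self, label: str | None = None) -> set[tuple[str, str]]:
        t = self.truth if label is None else self.truth[self.truth["species"] == label]
        return set(zip(t["reference_id"], t["target_id"]))

    def decoy_ids(self) -> set[str]:
        return set(self.hexaploid.decoy_ids) | set(self.diploid.decoy_ids)

    def write(self, outdir: str | os.PathLike) -> None:
        """Emit the full file bundle (FASTA/GFF3/TSV) under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([g.protein for g in self.reference.genes], out / "ref.faa")
        self.reference.metadata.to_csv(out / "ref_meta.tsv", sep="\t", index=False)
        write_gff3(self.reference.gene_models, out / "ref.gff3")
        for sp, stem in ((self.hexaploid, "targetA"), (self.diploid, "targetB")):
            write_fasta(sp.sequences, out / f"{stem}.faa")
            write_gff3(sp.gene_models, out / f"{stem}.gff3")
        write_interpro_tsv(self.domains, out / "domains.tsv")
        for label, expr in self.expression.items():
            write_expression(expr.matrix, out / f"expr{label}.tsv",
                             out / f"expr{label}_meta.tsv")
            write_fasta(expr.probes, out / f"probes{label}.fna")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the complete synthetic study deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    hexaploid = simulate_target_species(reference, config, "hexaploid", rng)
    diploid = simulate_target_species(reference, config, "diploid", rng)
    domains, family_domains = simulate_domains(reference, (hexaploid, diploid), config, rng)
    latents = _family_latents(reference, config, rng, config.n_tissues)
    expression = {
        hexaploid.label: simulate_expression(reference, hexaploid, config, rng, latents),
        diploid.label: simulate_expression(reference, diploid, config, rng, latents),
    }
    return SimulatedStudy(config=config, reference=reference, hexaploid=hexaploid,
                          diploid=diploid, domains=domains,
                          family_domains=family_domains, expression=expression)
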