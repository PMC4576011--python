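"""Structure, chromosome, domain and similarity characterization."""

import numpy as np
import pandas as pd
import pytest

from florthograph import comparative
from florthograph.comparative import (
    chromosome_distribution,
    domain_sharing_summary,
    group_similarity,
    longest_isoform,
    og_intron_comparison,
    placement_rate,
    shared_domains,
    structure_summary,
)
from florthograph.core_io import GeneModel, SequenceRecord, Transcript
from florthograph.orthology import OrthoGroup


def gene(gene_id, exon_sets, species="x", chromosome="c1"):
    transcripts = tuple(
        Transcript(transcript_id=f"{gene_id}.{i+1}", exons=tuple(exons))
        for i, exons in enumerate(exon_sets)
    )
    return GeneModel(gene_id=gene_id, species=species, transcripts=transcripts,
                     chromosome=chromosome)


# ---------------------------------------------------------------------------
# Structure summaries
# ---------------------------------------------------------------------------


def test_structure_summary_toy_arithmetic():
    g = gene("g1", [[(1, 100), (201, 300)]])
    s = structure_summary([g], None, "x")
    assert s.metrics["exons_per_gene"].mean == 2
    assert s.metrics["intron_size_bp"].mean == 100
    assert s.metrics["gene_length_bp"].mean == 300


def test_single_exon_genes_have_no_intron_stats():
    g = gene("g1", [[(1, 500)]])
    s = structure_summary([g], None, "x")
    assert s.metrics["intron_size_bp"] is None
    assert s.metrics["exon_size_bp"].mean == 500


def test_structure_summary_matches_bruteforce(small_study):
    """The summary equals an independent spreadsheet-style recomputation
    over the generator's raw exon intervals."""
    models = small_study.hexaploid.gene_models
    proteins = {r.id: r for r in small_study.hexaploid.sequences}
    s = structure_summary(models, proteins, "TA")

    # brute-force recomputation straight off the intervals
    tr_counts, glens, ex_counts, ex_sizes, in_sizes, plens = [], [], [], [], [], []
    for g in models:
        tr_counts.append(len(g.transcripts))
        spans = [(t.exons[0][0], t.exons[-1][1]) for t in g.transcripts]
        glens.append(max(e for _, e in spans) - min(s0 for s0, _ in spans) + 1)
        for t in g.transcripts:
            ex_counts.append(len(t.exons))
            for (a, b) in t.exons:
                ex_sizes.append(b - a + 1)
            if len(t.exons) > 1:
                for (_, e1), (s2, _) in zip(t.exons, t.exons[1:]):
                    in_sizes.append(s2 - 1 - (e1 + 1) + 1)
        if g.gene_id in proteins:
            plens.append(len(proteins[g.gene_id].residues))

    assert s.metrics["transcripts_per_gene"].mean == pytest.approx(np.mean(tr_counts))
    assert s.metrics["gene_length_bp"].mean == pytest.approx(np.mean(glens))
    assert s.metrics["exons_per_gene"].mean == pytest.approx(np.mean(ex_counts))
    assert s.metrics["exon_size_bp"].mean == pytest.approx(np.mean(ex_sizes))
    assert s.metrics["intron_size_bp"].mean == pytest.approx(np.mean(in_sizes))
    assert s.metrics["intron_size_bp"].min == min(in_sizes)
    assert s.metrics["intron_size_bp"].max == max(in_sizes)
    assert s.metrics["protein_length_aa"].mean == pytest.approx(np.mean(plens))


def test_min_mean_max_ordering(small_study):
    s = structure_summary(small_study.reference.gene_models, None, "AT")
    for name, m in s.metrics.items():
        if m is not None:
            assert m.min <= m.mean <= m.max


# ---------------------------------------------------------------------------
# OG intron comparison
# ---------------------------------------------------------------------------


def test_og_intron_comparison_intronless_flag():
    models = {
        "r1": gene("r1", [[(1, 400)]]),
        "t1": gene("t1", [[(1, 600)]]),
    }
    og = OrthoGroup(og_id="OG0001", members={"AT": ["r1"], "TA": ["t1"]})
    out = og_intron_comparison(og, models)
    assert out["intronless"] is True
    assert out["per_species"] == {"AT": None, "TA": None}


def test_og_intron_comparison_single_two_exon_gene():
    models = {
        "r1": gene("r1", [[(1, 100)]]),
        "t1": gene("t1", [[(1, 100), (2352, 2500)]]),  # intron 2251 bp
    }
    og = OrthoGroup(og_id="OG0001", members={"AT": ["r1"], "HV": ["t1"]})
    out = og_intron_comparison(og, models)
    assert out["per_species"]["HV"] == pytest.approx(2251)
    assert out["per_species"]["AT"] is None
    assert out["intronless"] is False


def test_og_intron_comparison_empty_og_error():
    with pytest.raises(ValueError):
        OrthoGroup(og_id="OG0001", members={})


# ---------------------------------------------------------------------------
# Chromosome distributions and placement
# ---------------------------------------------------------------------------


def _genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "functional_group",
                                       "chromosome", "position"])


def test_counts_independent_of_placement_seed():
    rows = [(f"g{i}", "photoperiod", "2H", None) for i in range(5)]
    lengths = {"2H": 1_000_000}
    d1 = chromosome_distribution(_genes_df(rows), lengths, seed=1)
    d2 = chromosome_distribution(_genes_df(rows), lengths, seed=2)
    assert d1.counts.loc["2H", "photoperiod"] == 5
    assert d1.counts.equals(d2.counts)
    assert not d1.coordinates["position"].equals(d2.coordinates["position"])
    # same seed -> identical coordinates
    d1b = chromosome_distribution(_genes_df(rows), lengths, seed=1)
    assert d1.coordinates.equals(d1b.coordinates)


def test_reference_subtotal_sums_to_190():
    counts = [48, 33, 32, 25, 52]
    rows = []
    for c, n in enumerate(counts, start=1):
        rows += [(f"g{c}_{i}", "regulation", f"AT{c}", i * 100) for i in range(n)]
    lengths = {f"AT{c}": 10_000_000 for c in range(1, 6)}
    d = chromosome_distribution(_genes_df(rows), lengths, seed=0)
    assert int(d.counts.to_numpy().sum()) == 190
    assert list(d.counts.sum(axis=1)) == counts


def test_unknown_chromosome_counts_unplaced():
    rows = [("g1", "regulation", "weird", 1), ("g2", "regulation", None, None)]
    d = chromosome_distribution(_genes_df(rows), {"1H": 100}, seed=0)
    assert d.n_unplaced == 2
    assert d.total == 2


def test_placement_rate_worked_example():
    rows = [(f"g{i}", "regulation", "3B", 100) for i in range(525)]
    rows += [(f"u{i}", "regulation", None, None) for i in range(375)]
    assert placement_rate(_genes_df(rows)) == 58


def test_placement_rate_extremes():
    rows = [(f"g{i}", "x", None, None) for i in range(10)]
    assert placement_rate(_genes_df(rows)) == 0
    rows = [(f"g{i}", "x", "1H", 5) for i in range(10)]
    assert placement_rate(_genes_df(rows)) == 100
    with pytest.raises(ValueError):
        placement_rate(_genes_df([]))


# ---------------------------------------------------------------------------
# Longest isoform
# ---------------------------------------------------------------------------


def rec(id_, n):
    return SequenceRecord(id=id_, residues="M" * n)


def test_longest_isoform_picks_longest():
    chosen = longest_isoform({"g": [rec("g.1", 300), rec("g.2", 450)]})
    assert chosen["g"].id == "g.2"


def test_longest_isoform_single():
    chosen = longest_isoform({"g": [rec("g.1", 10)]})
    assert chosen["g"].id == "g.1"


def test_longest_isoform_tie_breaks_by_id():
    chosen = longest_isoform({"g": [rec("g.2", 300), rec("g.1", 300)]})
    assert chosen["g"].id == "g.1"


# ---------------------------------------------------------------------------
# Shared domains
# ---------------------------------------------------------------------------


def _og3(ref=("r1",), ta=("t1",), hv=("h1",)):
    return OrthoGroup(og_id="OG0001",
                      members={"AT": list(ref), "TA": list(ta), "HV": list(hv)})


def test_domain_shared_across_all_species():
    domains = {"r1": {"IPR008914"}, "t1": {"IPR008914", "IPR000001"},
               "h1": {"IPR008914"}}
    assert shared_domains(_og3(), domains) == {"IPR008914"}


def test_domain_absent_from_one_species_not_shared():
    domains = {"r1": {"IPR000001"}, "t1": set(), "h1": {"IPR000001"}}
    assert shared_domains(_og3(), domains) == set()


def test_thirteen_shared_domains():
    ids = {f"IPR{i:06d}" for i in range(13)}
    domains = {"r1": ids, "t1": ids | {"IPR999999"}, "h1": ids}
    assert len(shared_domains(_og3(), domains)) == 13


def test_shared_domains_monotone_in_species():
    ids = {"IPR000001", "IPR000002"}
    domains = {"r1": ids, "t1": {"IPR000001"}, "h1": {"IPR000001"}}
    two = shared_domains(OrthoGroup(og_id="x", members={"AT": ["r1"], "TA": ["t1"]}), domains)
    three = shared_domains(_og3(), domains)
    assert three <= two


def test_domain_sharing_summary_worked_example():
    ogs = []
    domains = {}
    # 29 ineligible (reference only)
    for i in range(29):
        ogs.append(OrthoGroup(og_id=f"OGa{i}", members={"AT": [f"r{i}"]}))
    # 105 eligible sharing
    for i in range(105):
        r, t = f"rs{i}", f"ts{i}"
        ogs.append(OrthoGroup(og_id=f"OGb{i}", members={"AT": [r], "TA": [t]}))
        domains[r] = {"IPR000010"}
        domains[t] = {"IPR000010"}
    # 10 eligible not sharing
    for i in range(10):
        r, t = f"rn{i}", f"tn{i}"
        ogs.append(OrthoGroup(og_id=f"OGc{i}", members={"AT": [r], "TA": [t]}))
        domains[r] = {"IPR000020"}
        domains[t] = set()
    eligible, sharing, pct = domain_sharing_summary(ogs, domains)
    assert (eligible, sharing, pct) == (115, 105, 91)


def test_domain_sharing_summary_extremes():
    ogs = [OrthoGroup(og_id="a", members={"AT": ["r"], "TA": ["t"]})]
    assert domain_sharing_summary(ogs, {"r": {"IPR000001"}, "t": {"IPR000001"}})[2] == 100
    assert domain_sharing_summary(ogs, {})[2] == 0
    only_ref = [OrthoGroup(og_id="a", members={"AT": ["r"]})]
    assert domain_sharing_summary(only_ref, {}) == (0, 0, None)


def test_generator_family_domains_recovered(small_study, small_pipeline):
    """With the generator's conserved domain content, essentially every OG
    with target members shares at least one domain."""
    domains = {}
    for a in small_study.domains:
        domains.setdefault(a.protein_id, set()).add(a.interpro_id)
    eligible, sharing, pct = domain_sharing_summary(
        small_pipeline.orthogroups, domains,
        reference_species=small_study.config.reference_species)
    assert eligible > 0
    assert pct >= 80


# ---------------------------------------------------------------------------
# Group similarity
# ---------------------------------------------------------------------------


def test_group_similarity_identical_proteins():
    prots = {
        "r1": SequenceRecord(id="r1", residues="MKVLFWACDEMKVLFW"),
        "t1": SequenceRecord(id="t1", residues="MKVLFWACDEMKVLFW"),
        "r2": SequenceRecord(id="r2", residues="GHIKLMNPQRGHIKLM"),
        "t2": SequenceRecord(id="t2", residues="GHIKLMNPQRGHIKLM"),
    }
    ogs = [
        OrthoGroup(og_id="OG0001", members={"AT": ["r1"], "TA": ["t1"]}),
        OrthoGroup(og_id="OG0002", members={"AT": ["r2"], "TA": ["t2"]}),
    ]
    groups = {"r1": "photoperiod", "r2": "photoperiod"}
    out = group_similarity(ogs, prots, groups)
    assert len(out) == 1
    s = out[0]
    assert s.mean_similarity == 100.0
    assert s.sd_similarity == 0.0
    assert s.n_pairs == 2


def test_group_similarity_single_pair_sd_none():
    prots = {
        "r1": SequenceRecord(id="r1", residues="MKVLFWACDE"),
        "t1": SequenceRecord(id="t1", residues="MKVLFWACDE"),
    }
    ogs = [OrthoGroup(og_id="OG0001", members={"AT": ["r1"], "TA": ["t1"]})]
    out = group_similarity(ogs, prots, {"r1": "vernalization"})
    assert out[0].sd_similarity is None


def test_vernalization_least_conserved_in_generator(small_study, small_pipeline):
    """The generator plants vernalization families at the lowest identity, so
    their reference-vs-target similarity mean is the minimum across groups
    (for groups with enough pairs to average stably)."""
    study = small_study
    prots = {r.id: r for r in
             [g.protein for g in study.reference.genes]
             + study.hexaploid.sequences + study.diploid.sequences}
    groups = {g.gene_id: g.functional_group for g in study.reference.genes}
    ref_sp = study.config.reference_species
    out = group_similarity(small_pipeline.orthogroups, prots, groups,
                           reference_species=ref_sp)
    ref_target = [s for s in out if ref_sp in s.species_pair and s.n_pairs >= 2]
    assert ref_target
    by_group = {}
    for s in ref_target:
        by_group.setdefault(s.functional_group, []).append(s.mean_similarity)
    means = {g: np.mean(v) for g, v in by_group.items()}
    if "vernalization" in means and len(means) > 1:
        assert means["vernalization"] == min(means.values())
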