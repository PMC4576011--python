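"""Expression analysis: probe mapping, calls, tissue matching, clustering,
and ortholog profile comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from florthograph import expression
from florthograph.core_io import ExpressionMatrix, SequenceRecord
from florthograph.expression import (
    ExpressionParams,
    call_expressed,
    call_highly_expressed,
    collapse_replicates,
    gene_profiles,
    heatmap_export,
    hierarchical_cluster,
    map_probes_to_genes,
    match_tissues,
    og_expression_similarity,
)
from florthograph.orthology import OrthoGroup
from florthograph.simulate import EXTRA_DIPLOID_TISSUES, SHARED_TISSUES

from .oracles import complete_linkage_bruteforce


def matrix_from(values, samples, index=None):
    df = pd.DataFrame(values, index=index or [f"g{i}" for i in range(len(values))],
                      columns=[f"s{i}" for i in range(len(samples))])
    return ExpressionMatrix(values=df, samples=samples)


# ---------------------------------------------------------------------------
# Probe mapping
# ---------------------------------------------------------------------------


def nt(id_, residues):
    return SequenceRecord(id=id_, residues=residues, alphabet="nucleotide")


def test_exact_substring_probe_maps():
    rng = np.random.default_rng(0)
    gene_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    probe = nt("p1", gene_seq[100:300])
    table = map_probes_to_genes([probe], [nt("g1", gene_seq)])
    row = table.iloc[0]
    assert row["gene_id"] == "g1" and row["identity"] == 100.0


def test_low_identity_probe_unmapped():
    rng = np.random.default_rng(1)
    gene_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    probe_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    table = map_probes_to_genes([nt("p1", probe_seq)], [nt("g1", gene_seq)])
    assert table.iloc[0]["status"] == "unmapped"


def test_short_probe_rejected():
    table = map_probes_to_genes([nt("p1", "ACGT" * 10)], [nt("g1", "ACGT" * 100)])
    assert table.iloc[0]["status"] == "too-short"


def test_protein_input_is_error():
    with pytest.raises(ValueError):
        map_probes_to_genes([SequenceRecord(id="p", residues="MKV")],
                            [nt("g", "ACGT" * 50)])


def test_probe_mapping_matches_generator_truth(small_study):
    label = small_study.diploid.label
    expr = small_study.expression[label]
    table = map_probes_to_genes(expr.probes, expr.gene_nucleotides)
    mapped = dict(zip(table["probe_id"], table["gene_id"]))
    truth = dict(zip(expr.probe_mapping["probe_id"], expr.probe_mapping["gene_id"]))
    agree = sum(1 for p, g in truth.items() if mapped.get(p) == g)
    assert agree / len(truth) >= 0.99


# ---------------------------------------------------------------------------
# Replicates and calls
# ---------------------------------------------------------------------------


def test_collapse_replicates_mean():
    m = matrix_from([[4.0, 6.0, 8.0]], [("root", 1), ("root", 2), ("root", 3)])
    collapsed = collapse_replicates(m)
    assert collapsed.values.iloc[0, 0] == 6.0
    assert collapsed.samples == [("root", 1)]


def test_collapse_single_replicate_identity():
    m = matrix_from([[4.0, 7.0]], [("root", 1), ("leaf", 1)])
    collapsed = collapse_replicates(m)
    assert list(collapsed.values.iloc[0]) == [4.0, 7.0]


def test_collapse_matches_bruteforce_groupby():
    rng = np.random.default_rng(3)
    tissues = ["a", "b", "c"]
    samples = [(t, r + 1) for t in tissues for r in range(3)]
    vals = rng.normal(8, 2, size=(20, 9))
    m = matrix_from(vals, samples)
    collapsed = collapse_replicates(m)
    for ti, t in enumerate(tissues):
        expected = vals[:, 3 * ti:3 * ti + 3].mean(axis=1)
        assert np.allclose(collapsed.values[t].to_numpy(), expected)


@pytest.mark.parametrize("n_total,n_expr,expected", [(190, 189, 99), (900, 676, 75), (273, 248, 91)])
def test_expressed_percentages(n_total, n_expr, expected):
    """Count-level fixtures encoding the published expressed fractions."""
    params = ExpressionParams(detection_threshold=6.0)
    values = np.full((n_total, 2), 2.0)
    values[:n_expr, 0] = 9.0  # one tissue over threshold
    m = matrix_from(values, [("root", 1), ("leaf", 1)])
    _, (n, total, pct) = call_expressed(m, params)
    assert (n, total, pct) == (n_expr, n_total, expected)


def test_call_expressed_monotone_in_tau():
    rng = np.random.default_rng(4)
    m = matrix_from(rng.normal(6, 2, size=(50, 4)),
                    [("a", 1), ("b", 1), ("c", 1), ("d", 1)])
    counts = []
    for tau in (4.0, 5.0, 6.0, 7.0, 8.0):
        _, (n, _, _) = call_expressed(m, ExpressionParams(detection_threshold=tau))
        counts.append(n)
    assert counts == sorted(counts, reverse=True)


def test_high_expression_strict_boundary():
    m = matrix_from([[10.0, 10.0], [10.5, 10.5], [9.0, 12.0]],
                    [("a", 1), ("b", 1)], index=["at_boundary", "above", "mean_above"])
    high = call_highly_expressed(m)
    assert "at_boundary" not in high
    assert "above" in high
    assert "mean_above" in high  # mean 10.5 > 10


def test_highly_expressed_subset_of_expressed():
    rng = np.random.default_rng(5)
    samples = [(t, r + 1) for t in ("a", "b") for r in range(3)]
    m = matrix_from(rng.normal(8, 3, size=(100, 6)), samples)
    collapsed = collapse_replicates(m)
    flags, _ = call_expressed(collapsed, ExpressionParams(detection_threshold=6.0))
    high = call_highly_expressed(m)
    assert set(high) <= set(flags.index[flags])


def test_params_validation():
    with pytest.raises(ValueError):
        ExpressionParams(detection_threshold=11.0)


# ---------------------------------------------------------------------------
# Tissue matching
# ---------------------------------------------------------------------------


def test_tissue_matching_drops_extra_caryopsis_samples():
    a = list(SHARED_TISSUES)
    b = list(SHARED_TISSUES) + list(EXTRA_DIPLOID_TISSUES)
    shared = match_tissues(a, b)
    assert shared == a
    assert len(shared) == 13
    assert match_tissues(b, a) == a  # 15 -> 13, A-order preserved on shared


def test_tissue_matching_identity():
    a = ["x", "y", "z"]
    assert match_tissues(a, a) == a


def test_tissue_matching_disjoint_error():
    with pytest.raises(ValueError):
        match_tissues(["x"], ["y"])


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


def test_identical_columns_merge_first():
    rng = np.random.default_rng(6)
    vals = rng.normal(8, 2, size=(30, 4))
    vals[:, 3] = vals[:, 0]  # s3 duplicates s0
    df = pd.DataFrame(vals, columns=["s0", "s1", "s2", "s3"])
    Z, order = hierarchical_cluster(df, axis="columns")
    first_merge = {int(Z[0, 0]), int(Z[0, 1])}
    assert first_merge == {0, 3}
    assert Z[0, 2] == 0.0


def test_complete_linkage_matches_bruteforce():
    rng = np.random.default_rng(7)
    for _ in range(5):
        pts = rng.normal(size=(5, 3))
        df = pd.DataFrame(pts.T)  # columns are points
        Z, _ = hierarchical_cluster(df, axis="columns")
        assert np.allclose(sorted(Z[:, 2]), sorted(complete_linkage_bruteforce(pts)))


def test_single_column_trivial_dendrogram():
    df = pd.DataFrame({"only": [1.0, 2.0]})
    Z, order = hierarchical_cluster(df, axis="columns")
    assert Z is None and order == ["only"]


def test_heatmap_export_deterministic(tmp_path):
    rng = np.random.default_rng(8)
    samples = [(t, 1) for t in ("a", "b", "c")]
    m = matrix_from(rng.normal(8, 2, size=(10, 3)), samples)
    p1, p2 = tmp_path / "h1.tsv", tmp_path / "h2.tsv"
    o1 = heatmap_export(m, p1)
    o2 = heatmap_export(m, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert o1 == o2
    # leaf order in the TSV matches the clustering output
    back = pd.read_csv(p1, sep="\t", index_col=0)
    assert list(back.index) == o1["rows"]
    assert list(back.columns) == o1["columns"]


# ---------------------------------------------------------------------------
# Ortholog profile comparison
# ---------------------------------------------------------------------------


def test_identical_profiles_correlate_perfectly():
    pa = pd.DataFrame([[7.0, 8.0, 9.0, 10.0]], index=["a1"])
    pb = pd.DataFrame([[7.0, 8.0, 9.0, 10.0]], index=["b1"])
    pb.columns = pa.columns
    og = OrthoGroup(og_id="OG0001", members={"TA": ["a1"], "HV": ["b1"]})
    pairs = og_expression_similarity([og], pa, pb, "TA", "HV")
    assert pairs[0].correlation == pytest.approx(1.0)


def test_negated_profile_correlates_minus_one():
    base = np.array([7.0, 8.0, 9.0, 10.0])
    neg = 2 * base.mean() - base
    pa = pd.DataFrame([base], index=["a1"])
    pb = pd.DataFrame([neg], index=["b1"], columns=pa.columns)
    og = OrthoGroup(og_id="OG0001", members={"TA": ["a1"], "HV": ["b1"]})
    pairs = og_expression_similarity([og], pa, pb, "TA", "HV")
    assert pairs[0].correlation == pytest.approx(-1.0)


def test_correlation_invariant_to_affine_rescaling():
    rng = np.random.default_rng(9)
    base = rng.normal(8, 2, 6)
    other = rng.normal(8, 2, 6)
    pa = pd.DataFrame([base], index=["a1"])
    og = OrthoGroup(og_id="OG0001", members={"TA": ["a1"], "HV": ["b1"]})

    def corr(profile_b):
        pb = pd.DataFrame([profile_b], index=["b1"], columns=pa.columns)
        return og_expression_similarity([og], pa, pb, "TA", "HV")[0].correlation

    r0 = corr(other)
    assert corr(0.5 * other + 3.0) == pytest.approx(r0)


def test_inactive_partner_flagged():
    pa = pd.DataFrame([[8.0, 9.0, 10.0, 7.0]], index=["a1"])
    pb = pd.DataFrame([[2.0, 2.1, 1.9, 2.0]], index=["b1"], columns=pa.columns)
    og = OrthoGroup(og_id="OG0001", members={"TA": ["a1"], "HV": ["b1"]})
    p = og_expression_similarity([og], pa, pb, "TA", "HV")[0]
    assert p.status == "inactive-partner"
    assert p.correlation is None
    assert p.a_expressed and not p.b_expressed


def test_unmapped_member_flagged():
    pa = pd.DataFrame([[8.0, 9.0]], index=["a1"])
    pb = pd.DataFrame([[8.0, 9.0]], index=["other"], columns=pa.columns)
    og = OrthoGroup(og_id="OG0001", members={"TA": ["a1"], "HV": ["b1"]})
    p = og_expression_similarity([og], pa, pb, "TA", "HV")[0]
    assert p.status == "unmapped"


def test_mismatched_tissue_columns_error():
    pa = pd.DataFrame([[8.0, 9.0]], index=["a1"], columns=["x", "y"])
    pb = pd.DataFrame([[8.0, 9.0]], index=["b1"], columns=["y", "x"])
    og = OrthoGroup(og_id="OG0001", members={"TA": ["a1"], "HV": ["b1"]})
    with pytest.raises(ValueError):
        og_expression_similarity([og], pa, pb, "TA", "HV")


# ---------------------------------------------------------------------------
# Planted-correlation recovery on the generator
# ---------------------------------------------------------------------------


def planted_correlation_error(rho, seed, n_pairs=200, n_tissues=13):
    """Generate correlated ortholog tissue-mean profiles the way the study
    generator does, then measure the mean recovered Pearson correlation."""
    from florthograph import simulate

    cfg = simulate.SimulationConfig(seed=seed, profile_correlation=rho,
                                    noise_sd=0.5)
    rng = np.random.default_rng(seed)
    dilution = cfg.profile_sd**2 / (cfg.profile_sd**2 + cfg.noise_sd**2 / cfg.n_replicates)
    r_latent = min(1.0, rho / dilution) if rho > 0 else 0.0
    rs = []
    for _ in range(n_pairs):
        z = rng.normal(0, 1, n_tissues)
        profiles = []
        for _member in range(2):
            eps = rng.normal(0, 1, n_tissues)
            mean_profile = cfg.profile_baseline + cfg.profile_sd * (
                np.sqrt(r_latent) * z + np.sqrt(max(0.0, 1 - r_latent)) * eps)
            reps = np.repeat(mean_profile, cfg.n_replicates) + rng.normal(
                0, cfg.noise_sd, n_tissues * cfg.n_replicates)
            profiles.append(reps.reshape(n_tissues, cfg.n_replicates).mean(axis=1))
        rs.append(np.corrcoef(profiles[0], profiles[1])[0, 1])
    return float(np.mean(rs))


@pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
def test_planted_profile_correlation_recovered(rho):
    recovered = planted_correlation_error(rho, seed=123)
    assert abs(recovered - rho) <= 0.1


def test_pipeline_level_correlation_recovery(small_study, small_pipeline):
    """End to end: collapse the generated replicate matrices, match tissues,
    and compare ortholog profiles within predicted OGs; the mean correlation
    of active pairs approaches the configured value."""
    study = small_study
    ta, hv = study.hexaploid.label, study.diploid.label
    mats = {}
    for label in (ta, hv):
        collapsed = collapse_replicates(study.expression[label].matrix)
        truth_map = study.expression[label].probe_mapping
        mapping = pd.DataFrame({
            "probe_id": truth_map["probe_id"], "gene_id": truth_map["gene_id"],
            "identity": 100.0, "status": "mapped"})
        mats[label] = gene_profiles(collapsed, mapping)
    shared = match_tissues(list(mats[ta].columns), list(mats[hv].columns))
    pa, pb = mats[ta][shared], mats[hv][shared]
    pairs = og_expression_similarity(small_pipeline.orthogroups, pa, pb, ta, hv)
    active = [p.correlation for p in pairs if p.status == "ok"]
    assert len(active) >= 10
    assert abs(np.mean(active) - study.config.profile_correlation) <= 0.15


def test_pseudogenes_flagged_unexpressed(small_study):
    """Generated pseudogene rows fall below the default detection threshold
    in every tissue."""
    study = small_study
    found = 0
    for sp in (study.hexaploid, study.diploid):
        label = sp.label
        matrix = collapse_replicates(study.expression[label].matrix)
        flags, _ = call_expressed(matrix)
        probe_of = {g: p for p, g in zip(study.expression[label].probe_mapping["probe_id"],
                                         study.expression[label].probe_mapping["gene_id"])}
        for row in sp.truth.itertuples():
            if row.pseudogene:
                found += 1
                assert not flags[probe_of[row.target_id]]
    assert found > 0
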