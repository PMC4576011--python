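"""In-silico expression analysis of predicted flowering genes.

Probe-set to gene mapping, expressed / highly-expressed calls on normalized
log2 intensities, tissue matching across species, complete-linkage
hierarchical clustering for heatmaps, and cross-species comparison of
ortholog expression profiles within orthogroups.

The input contract is a *normalized, log2-transformed* matrix (probe sets or
genes x tissue-replicate samples); array-level normalization is upstream of
this package.  "Expressed" means at least one tissue mean reaches the
detection threshold tau (default 6.0 log2 units — the chips behind the
original presence calls define no intensity cutoff, so tau is an explicit,
configurable choice).  "Highly expressed" is a grand mean over all
replicate-level samples strictly above 10 log2 units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr

from .core_io import ExpressionMatrix, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionParams:
    """Thresholds and methods for the expression analyses.

    ``detection_threshold`` (tau) is the log2 level a tissue mean must reach
    for a gene to count as expressed in that tissue; the high-expression rule
    is a strict ``> high_expression_threshold`` on the grand mean over all
    replicate-level samples.
    """

    detection_threshold: float = 6.0
    high_expression_threshold: float = 10.0
    linkage: str = "complete"
    distance_metric: str = "euclidean"       # or "correlation"
    correlation_method: str = "pearson"      # or "spearman", for ortholog pairs

    def __post_init__(self) -> None:
        if self.detection_threshold >= self.high_expression_threshold:
            raise ValueError("detection threshold must lie below the high-expression threshold")
        if self.linkage != "complete":
            raise ValueError("only complete linkage is supported")
        if self.distance_metric not in ("euclidean", "correlation"):
            raise ValueError("distance_metric must be 'euclidean' or 'correlation'")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be 'pearson' or 'spearman'")


@dataclass(frozen=True)
class ProfilePair:
    """One cross-species ortholog pair with its expression-profile comparison."""

    gene_a: str
    gene_b: str
    og_id: str
    correlation: float | None
    a_expressed: bool
    b_expressed: bool
    status: str = "ok"       # ok | inactive-partner | unmapped | constant

    def __post_init__(self) -> None:
        if self.correlation is not None and not -1.0000001 <= self.correlation <= 1.0000001:
            raise ValueError("correlation must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Probe mapping
# ---------------------------------------------------------------------------


def map_probes_to_genes(
    probe_targets: Sequence[SequenceRecord],
    gene_seqs: Sequence[SequenceRecord],
    min_identity: float = 95.0,
    min_len: int = 100,
) -> pd.DataFrame:
    """Map each probe-set target sequence to its best-matching gene.

    Identity is computed from the best infix (probe-within-gene) alignment:
    ``100 * (1 - edit_distance / probe_length)``.  A probe maps to the gene
    with the highest identity (ties break to the smaller gene id) when that
    identity reaches ``min_identity`` and the probe is at least ``min_len``
    nucleotides; otherwise it is unmapped.  Genes targeted by several probe
    sets keep all of them, flagged ``multi_probe``.
    """
    import edlib

    for rec in list(probe_targets) + list(gene_seqs):
        if rec.alphabet != "nucleotide":
            raise ValueError(f"sequence {rec.id!r} is not nucleotide; probe mapping "
                             "operates on transcript/probe target sequences")
    rows = []
    for probe in probe_targets:
        if len(probe) < min_len:
            rows.append({"probe_id": probe.id, "gene_id": None,
                         "identity": None, "status": "too-short"})
            continue
        best_gene, best_identity = None, -1.0
        for gene in gene_seqs:
            res = edlib.align(probe.residues, gene.residues, mode="HW", task="distance")
            dist = res["editDistance"]
            if dist < 0:
                continue
            identity = 100.0 * (1.0 - dist / len(probe))
            if identity > best_identity or (identity == best_identity
                                            and best_gene is not None and gene.id < best_gene):
                best_gene, best_identity = gene.id, identity
        if best_gene is not None and best_identity >= min_identity:
            rows.append({"probe_id": probe.id, "gene_id": best_gene,
                         "identity": best_identity, "status": "mapped"})
        else:
            rows.append({"probe_id": probe.id, "gene_id": None,
                         "identity": None if best_gene is None else best_identity,
                         "status": "unmapped"})
    table = pd.DataFrame(rows, columns=["probe_id", "gene_id", "identity", "status"])
    dup = table["gene_id"].dropna().duplicated(keep=False)
    table["multi_probe"] = False
    table.loc[table["gene_id"].notna() & dup.reindex(table.index, fill_value=False), "multi_probe"] = True
    return table


def gene_profiles(matrix: ExpressionMatrix, mapping: pd.DataFrame) -> pd.DataFrame:
    """Per-gene profiles from a probe-level matrix.

    A gene hit by several probe sets gets the arithmetic mean of their
    profiles.  Rows of the matrix not mapped to a gene are dropped.
    """
    mapped = mapping[mapping["status"] == "mapped"]
    frames: dict[str, list[str]] = {}
    for row in mapped.itertuples():
        frames.setdefault(row.gene_id, []).append(row.probe_id)
    out = {}
    for gene, probes in frames.items():
        present = [p for p in probes if p in matrix.values.index]
        if present:
            out[gene] = matrix.values.loc[present].mean(axis=0)
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# Replicates and calls
# ---------------------------------------------------------------------------


def collapse_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-tissue arithmetic mean of the replicate columns.

    Output columns follow the declared tissue order (first appearance in the
    sample list); each tissue appears once, as replicate 1.
    """
    tissues = matrix.tissues
    cols = {}
    for tissue in tissues:
        members = [c for c, (t, _r) in zip(matrix.values.columns, matrix.samples) if t == tissue]
        cols[tissue] = matrix.values[members].mean(axis=1)
    collapsed = pd.DataFrame(cols, index=matrix.values.index)
    return ExpressionMatrix(values=collapsed, samples=[(t, 1) for t in tissues])


def call_expressed(
    tissue_matrix: ExpressionMatrix,
    params: ExpressionParams | None = None,
) -> tuple[pd.Series, tuple[int, int, int]]:
    """Expressed-in-at-least-one-tissue calls on a collapsed matrix.

    A gene is expressed iff any tissue mean is >= tau.  Returns the per-gene
    boolean series and a ``(n_expressed, total, integer %)`` summary.
    """
    params = params or ExpressionParams()
    flags = (tissue_matrix.values >= params.detection_threshold).any(axis=1)
    total = len(flags)
    n = int(flags.sum())
    pct = int(np.floor(100.0 * n / total + 0.5)) if total else 0
    return flags, (n, total, pct)


def call_highly_expressed(
    matrix: ExpressionMatrix,
    params: ExpressionParams | None = None,
) -> list[str]:
    """Genes whose grand mean log2 over ALL replicate-level samples strictly
    exceeds the high-expression threshold (boundary value excluded)."""
    params = params or ExpressionParams()
    grand = matrix.values.mean(axis=1)
    return list(grand.index[grand > params.high_expression_threshold])


def match_tissues(samples_a: Sequence[str], samples_b: Sequence[str]) -> list[str]:
    """Shared tissue labels, ordered as in species A; dropped labels logged.

    An empty intersection is a hard error (no comparison is possible).
    """
    set_b = set(samples_b)
    shared = [t for t in dict.fromkeys(samples_a) if t in set_b]
    if not shared:
        raise ValueError("no shared tissue labels between the two species")
    dropped_a = [t for t in dict.fromkeys(samples_a) if t not in set_b]
    dropped_b = [t for t in dict.fromkeys(samples_b) if t not in set(samples_a)]
    for side, dropped in (("A", dropped_a), ("B", dropped_b)):
        if dropped:
            logger.info("tissue matching dropped %d species-%s samples: %s",
                        len(dropped), side, dropped)
    return shared


# ---------------------------------------------------------------------------
# Clustering and heatmaps
# ---------------------------------------------------------------------------


def hierarchical_cluster(
    values: pd.DataFrame,
    axis: str = "columns",
    params: ExpressionParams | None = None,
) -> tuple[np.ndarray | None, list[str]]:
    """Agglomerative complete-linkage clustering of rows or columns.

    Returns the SciPy linkage matrix and the dendrogram leaf order (labels).
    With a single item the dendrogram is trivial.  SciPy's deterministic
    merge order (smaller-index cluster first on ties) makes the leaf order
    reproducible.
    """
    params = params or ExpressionParams()
    data = values.T if axis == "columns" else values
    labels = list(data.index)
    if len(labels) < 2:
        return None, labels
    dist = pdist(data.to_numpy(), metric=params.distance_metric)
    Z = linkage(dist, method=params.linkage)
    order = [labels[i] for i in leaves_list(Z)]
    return Z, order


def heatmap_export(
    matrix: ExpressionMatrix,
    tsv_path,
    svg_path=None,
    params: ExpressionParams | None = None,
) -> dict[str, list[str]]:
    """Cluster both axes, write the reordered matrix as TSV (the bit-exact,
    testable artifact) and optionally an SVG rendering.

    Returns the leaf orders (``{"rows": [...], "columns": [...]}``).
    """
    params = params or ExpressionParams()
    _, row_order = hierarchical_cluster(matrix.values, axis="rows", params=params)
    _, col_order = hierarchical_cluster(matrix.values, axis="columns", params=params)
    ordered = matrix.values.loc[row_order, col_order]
    ordered.to_csv(tsv_path, sep="\t", index_label="id", float_format="%.6g")
    if svg_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(4, 0.3 * ordered.shape[1]),
                                        max(3, 0.12 * ordered.shape[0])))
        im = ax.pcolormesh(ordered.to_numpy(), cmap="viridis")
        ax.set_xticks(np.arange(ordered.shape[1]) + 0.5)
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, label="log2 expression")
        fig.tight_layout()
        fig.savefig(svg_path)
        plt.close(fig)
    return {"rows": row_order, "columns": col_order}


# ---------------------------------------------------------------------------
# Ortholog profile comparison
# ---------------------------------------------------------------------------


def og_expression_similarity(
    ogs: Sequence,
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    species_a: str,
    species_b: str,
    params: ExpressionParams | None = None,
) -> list[ProfilePair]:
    """Expression-profile correlation for every cross-species ortholog pair.

    ``profiles_a``/``profiles_b`` are collapsed, tissue-matched per-gene
    matrices (identical column order).  For each orthogroup, every
    (species-A member, species-B member) pair is reported: Pearson (or
    Spearman) correlation over the shared tissues, the two expressed flags,
    and a status — ``unmapped`` when a member has no profile,
    ``inactive-partner`` (correlation ``None``) when an expressed profile is
    paired with an unexpressed one, ``constant`` when either profile has zero
    variance.
    """
    params = params or ExpressionParams()
    if list(profiles_a.columns) != list(profiles_b.columns):
        raise ValueError("profiles must be tissue-matched (identical column order)")
    tau = params.detection_threshold
    out: list[ProfilePair] = []
    for og in ogs:
        for a in og.members.get(species_a, []):
            for b in og.members.get(species_b, []):
                if a not in profiles_a.index or b not in profiles_b.index:
                    out.append(ProfilePair(gene_a=a, gene_b=b, og_id=og.og_id,
                                           correlation=None, a_expressed=False,
                                           b_expressed=False, status="unmapped"))
                    continue
                pa = profiles_a.loc[a].to_numpy()
                pb = profiles_b.loc[b].to_numpy()
                a_expr = bool((pa >= tau).any())
                b_expr = bool((pb >= tau).any())
                if not (a_expr and b_expr):
                    out.append(ProfilePair(gene_a=a, gene_b=b, og_id=og.og_id,
                                           correlation=None, a_expressed=a_expr,
                                           b_expressed=b_expr, status="inactive-partner"))
                    continue
                if np.std(pa) == 0 or np.std(pb) == 0:
                    out.append(ProfilePair(gene_a=a, gene_b=b, og_id=og.og_id,
                                           correlation=None, a_expressed=a_expr,
                                           b_expressed=b_expr, status="constant"))
                    continue
                if params.correlation_method == "pearson":
                    r = float(pearsonr(pa, pb).statistic)
                else:
                    r = float(spearmanr(pa, pb).statistic)
                out.append(ProfilePair(gene_a=a, gene_b=b, og_id=og.og_id,
                                       correlation=r, a_expressed=a_expr,
                                       b_expressed=b_expr, status="ok"))
    return out


def profile_pair_table(pairs: Sequence[ProfilePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "og_id": p.og_id, "gene_a": p.gene_a, "gene_b": p.gene_b,
                "correlation": p.correlation, "a_expressed": p.a_expressed,
                "b_expressed": p.b_expressed, "status": p.status,
            }
            for p in pairs
        ],
        columns=["og_id", "gene_a", "gene_b", "correlation",
                 "a_expressed", "b_expressed", "status"],
    )
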