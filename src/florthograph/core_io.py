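"""Validated in-memory types and readers/writers for every external format.

Formats handled: FASTA (protein and nucleotide), GFF3 gene models,
12-column tabular similarity-search hits (the classic ``outfmt 6`` dialect,
so externally produced BLAST tables are interchangeable with the internal
aligner's output), InterProScan-style TSV domain annotations, and normalized
log2 expression matrices with a sidecar sample-metadata table.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive, so an
interval's length is ``end - start + 1``.  Residues are stored uppercase;
parsing is case-insensitive.
"""

from __future__ import annotations

import logging
import math
import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

Alphabet = Literal["protein", "nucleotide"]

# IUPAC letters, plus stop (*) for translated ORFs.
_PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")
_NUCLEOTIDE_LETTERS = frozenset("ACGTUNRYSWKMBDHV")

_INTERPRO_RE = re.compile(r"^IPR\d{6}$")

#: Column order of the 12-column tabular hit format.
HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """An identified biological sequence with an explicit alphabet tag."""

    id: str
    residues: str
    description: str = ""
    alphabet: Alphabet = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = _PROTEIN_LETTERS if self.alphabet == "protein" else _NUCLEOTIDE_LETTERS
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains letters {sorted(bad)} "
                f"not in the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | os.PathLike, alphabet: Alphabet = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; wrapped sequence lines are concatenated.  A duplicate
    id or an empty sequence under a header is a hard error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if not residues:
            raise FormatError(f"empty sequence under header {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc, alphabet=alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records to FASTA, wrapping residues at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    """One transcript: an ordered list of exon intervals (1-based, inclusive)."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id!r} has no exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if s > e:
                raise ValueError(f"transcript {self.transcript_id!r}: exon start {s} > end {e}")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"transcript {self.transcript_id!r}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons; count = exon_count - 1."""
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def intron_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.introns]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcripts, strand, and (optional) chromosome position."""

    gene_id: str
    species: str
    transcripts: tuple[Transcript, ...]
    chromosome: str | None = None
    strand: Literal["+", "-", "unknown"] = "unknown"
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id!r} has no transcripts")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        lo = min(t.span[0] for t in self.transcripts)
        hi = max(t.span[1] for t in self.transcripts)
        start = lo if self.start is None else min(self.start, lo)
        end = hi if self.end is None else max(self.end, hi)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    @property
    def length(self) -> int:
        """Gene-feature span in bp (covers all transcript spans)."""
        return self.end - self.start + 1


def _seqid_to_chromosome(seqid: str, chromosomes: set[str] | None) -> str | None:
    if chromosomes is not None:
        return seqid if seqid in chromosomes else None
    low = seqid.lower()
    if low.startswith(("scaffold", "contig", "unplaced")):
        return None
    return seqid


def read_gff3(
    path: str | os.PathLike,
    species: str = "unknown",
    chromosomes: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Reconstruct the gene -> transcript -> exon hierarchy from a GFF3 file.

    Genes sitting on unplaced scaffolds (seqid not in ``chromosomes`` when a
    vocabulary is given, otherwise a seqid that looks like a scaffold/contig)
    yield ``chromosome = None``.  An exon whose Parent cannot be resolved is
    skipped with a logged warning; an mRNA without exons is a hard error.
    """
    import gffutils

    chrom_set = set(chromosomes) if chromosomes is not None else None
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    known_transcripts = {
        f.id for f in db.all_features() if f.featuretype in ("mRNA", "transcript")
    }
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not any(p in known_transcripts for p in parents):
            logger.warning("exon at %s:%s-%s has no resolvable Parent; skipped",
                           exon.seqid, exon.start, exon.end)

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [(e.start, e.end) for e in db.children(t, featuretype="exon", order_by="start")]
            if not exons:
                raise FormatError(f"mRNA {t.id!r} in {path} has no exons")
            transcripts.append(Transcript(transcript_id=t.id, exons=tuple(exons)))
        if not transcripts:
            raise FormatError(f"gene {g.id!r} in {path} has no transcripts")
        strand = g.strand if g.strand in ("+", "-") else "unknown"
        genes.append(
            GeneModel(
                gene_id=g.id,
                species=species,
                transcripts=tuple(transcripts),
                chromosome=_seqid_to_chromosome(g.seqid, chrom_set),
                strand=strand,
                start=g.start,
                end=g.end,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as a minimal, valid GFF3 file (gene/mRNA/exon)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            seqid = g.chromosome if g.chromosome is not None else f"scaffold_{g.gene_id}"
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{seqid}\tflorthograph\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                s, e = t.span
                fh.write(
                    f"{seqid}\tflorthograph\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for (es, ee) in t.exons:
                    fh.write(
                        f"{seqid}\tflorthograph\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Pairwise-hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One pairwise search result in the 12-column tabular dialect."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must lie in [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


def read_hit_table(path: str | os.PathLike) -> list[HitRecord]:
    """Parse a 12-column tab-delimited hit table (scientific-notation E-values OK)."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-delimited columns, got {len(parts)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bit_score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.evalue:.2e}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Domain annotations (InterProScan-style TSV)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain match on a protein; rows without an integrated accession
    (``IPR`` + 6 digits) are retained but flagged un-integrable."""

    protein_id: str
    start: int
    end: int
    interpro_id: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain on {self.protein_id!r}: start {self.start} > end {self.end}")
        if self.interpro_id is not None and not _INTERPRO_RE.match(self.interpro_id):
            raise ValueError(f"malformed InterPro accession {self.interpro_id!r}")

    @property
    def un_integrable(self) -> bool:
        return self.interpro_id is None


def read_interpro_tsv(path: str | os.PathLike) -> list[DomainAnnotation]:
    """Read an InterProScan TSV (protein id in column 1, match coordinates in
    columns 7-8, InterPro accession in column 12 when present).

    Rows with unreadable coordinates are skipped with a warning.
    """
    annotations: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                logger.warning("%s: line %d: fewer than 8 columns; skipped", path, lineno)
                continue
            try:
                start, end = int(parts[6]), int(parts[7])
            except ValueError:
                logger.warning("%s: line %d: unreadable coordinates; skipped", path, lineno)
                continue
            ipr = parts[11].strip() if len(parts) > 11 else ""
            ipr_id = ipr if _INTERPRO_RE.match(ipr) else None
            desc = parts[12].strip() if len(parts) > 12 else ""
            annotations.append(
                DomainAnnotation(
                    protein_id=parts[0],
                    start=start,
                    end=end,
                    interpro_id=ipr_id,
                    description=desc,
                )
            )
    return annotations


def write_interpro_tsv(annotations: Iterable[DomainAnnotation], path: str | os.PathLike) -> None:
    """Write domain annotations in the InterProScan 13-column TSV layout."""
    with open(path, "w") as fh:
        for a in annotations:
            length = a.end  # sequence length unknown; end coordinate is a lower bound
            fh.write(
                "\t".join(
                    [
                        a.protein_id,
                        "-",  # md5
                        str(length),
                        "synthetic",  # analysis
                        a.interpro_id or "SYN_UNINTEGRATED",
                        a.description,
                        str(a.start),
                        str(a.end),
                        "0.0",
                        "T",
                        "-",  # date
                        a.interpro_id or "",
                        a.description,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes/probe-sets x (tissue, replicate) matrix of log2 intensities.

    ``values`` is a complete DataFrame (rows = probe-set or gene ids, columns
    = sample ids); ``samples`` maps each column, in order, to a
    ``(tissue_label, replicate_index)`` pair.
    """

    values: pd.DataFrame
    samples: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.samples) != self.values.shape[1]:
            raise ValueError("one (tissue, replicate) pair required per column")
        if self.values.isna().any().any():
            na = self.values.stack()[self.values.stack().isna()]
            raise ValueError(f"missing expression cells: {list(na.index[:3])} ...")
        for tissue, rep in self.samples:
            if rep < 1:
                raise ValueError(f"replicate index must be >= 1 (tissue {tissue!r})")

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in declared order (first appearance)."""
        seen: list[str] = []
        for tissue, _ in self.samples:
            if tissue not in seen:
                seen.append(tissue)
        return seen

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)


def read_expression(path: str | os.PathLike, metadata_path: str | os.PathLike,
                    tissue_vocabulary: Iterable[str] | None = None) -> ExpressionMatrix:
    """Read a TSV expression matrix plus its sidecar sample-metadata TSV.

    The metadata file has columns ``sample_id``, ``tissue``, ``replicate``.
    Every matrix column must be described; a missing/non-numeric cell and a
    tissue with no replicate are hard errors.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "tissue": str})
    required = {"sample_id", "tissue", "replicate"}
    if not required <= set(meta.columns):
        raise FormatError(f"{metadata_path}: missing metadata columns {required - set(meta.columns)}")
    values = pd.read_csv(path, sep="\t", index_col=0)
    for col in values.columns:
        bad = values[col][~values[col].apply(lambda v: isinstance(v, (int, float)) and not (isinstance(v, float) and math.isnan(v)))]
        if len(bad):
            raise FormatError(f"{path}: non-numeric or missing cell at row {bad.index[0]!r}, column {col!r}")
    meta_map = {row.sample_id: (row.tissue, int(row.replicate)) for row in meta.itertuples()}
    samples = []
    for col in values.columns:
        if col not in meta_map:
            raise FormatError(f"{path}: sample column {col!r} absent from metadata")
        samples.append(meta_map[col])
    if tissue_vocabulary is not None:
        vocab = set(tissue_vocabulary)
        unknown = {t for t, _ in samples} - vocab
        if unknown:
            raise FormatError(f"tissue labels {sorted(unknown)} not in declared vocabulary")
    return ExpressionMatrix(values=values.astype(float), samples=samples)


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike,
                     metadata_path: str | os.PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="id", float_format="%.6g")
    meta = pd.DataFrame(
        {
            "sample_id": list(matrix.values.columns),
            "tissue": [t for t, _ in matrix.samples],
            "replicate": [r for _, r in matrix.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)
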