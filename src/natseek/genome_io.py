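"""Readers, writers and domain types for every external format the pipeline touches.

All interval logic in :mod:`natseek` runs on a single internal convention:
0-based, half-open coordinates on a named scaffold with an explicit strand.
GFF3 and GTF use 1-based closed coordinates; the conversion happens here, at
the I/O boundary, and nowhere else.

Strand-specificity is the whole point of antisense-transcript detection, so
unstranded (``.``) features are rejected rather than guessed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")
ALPHABET = set("ACGTN")

#: sources a transcript model can come from
SOURCE_GENE = "predicted_gene"
SOURCE_ASSEMBLED = "assembled"


class Span(NamedTuple):
    """A strandless, 0-based half-open coordinate range.

    Used for overlap regions shared between opposite-strand transcripts and
    for offsets within a spliced sequence, where a genomic strand does not
    apply.
    """

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a scaffold (0-based, half-open)."""

    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base on the same
        scaffold (strand is ignored: overlap is a genomic notion)."""
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_span(self, other: "GenomicInterval") -> Span | None:
        """The shared region, or None if the intervals do not overlap."""
        if not self.overlaps(other):
            return None
        return Span(max(self.start, other.start), min(self.end, other.end))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript or gene model.

    The unit compared for overlap and complementarity throughout the
    pipeline. ``sequence``, when present, is the spliced sequence read
    5'->3' on the model's own strand.
    """

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    source: str = SOURCE_ASSEMBLED
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.source not in (SOURCE_GENE, SOURCE_ASSEMBLED):
            raise ValueError(f"unknown source {self.source!r}")
        if not self.exons:
            raise ValueError(f"{self.id}: transcript must have at least one exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for exon in self.exons:
            if exon.scaffold != self.interval.scaffold or exon.strand != self.interval.strand:
                raise ValueError(f"{self.id}: exon scaffold/strand differs from transcript")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.id}: overlapping exons")
        if self.exons[0].start != self.interval.start or self.exons[-1].end != self.interval.end:
            raise ValueError(f"{self.id}: exon chain does not span the transcript interval")
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise ValueError(f"{self.id}: sequence length != sum of exon lengths")

    @property
    def scaffold(self) -> str:
        return self.interval.scaffold

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass
class ExpressionMatrix:
    """Transcript x stage abundance table.

    ``values`` is indexed by transcript id with one column per stage, every
    cell filled and non-negative. ``unit`` records whether the numbers are
    RPKM or raw counts; presence calls only make sense for RPKM.
    """

    values: pd.DataFrame
    unit: str = "RPKM"

    def __post_init__(self) -> None:
        if self.unit not in ("RPKM", "raw_count"):
            raise ValueError(f"unknown expression unit {self.unit!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix has missing cells")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated transcript rows: {dupes}")

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def value(self, transcript_id: str, stage: str) -> float:
        return float(self.values.at[transcript_id, stage])

    def profile(self, transcript_id: str) -> pd.Series:
        return self.values.loc[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.values.index


@dataclass
class EvidenceTables:
    """Pluggable stand-ins for external database searches.

    Each mapping goes from transcript id to the best (smallest) e-value of a
    BLAST-style search, or to a coding-potential score; an absent id means
    "no hit". A table set to None means the search was not run at all, which
    the filter cascade treats as a vacuous pass (with a warning) unless
    strict mode is on.
    """

    nr_best_evalue: dict[str, float] | None = None
    cpc_score: dict[str, float] | None = None
    housekeeping_best_evalue: dict[str, float] | None = None
    smallrna_best_evalue: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("nr_best_evalue", "housekeeping_best_evalue", "smallrna_best_evalue"):
            table = getattr(self, name)
            if table is not None and any(v <= 0 for v in table.values()):
                raise ValueError(f"{name}: e-values must be > 0")


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def canonicalize(seq: str) -> str:
    """Uppercase and validate against the ACGTN alphabet."""
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"sequence contains characters outside ACGTN: {sorted(bad)}")
    return seq


def load_genome(path: str | Path):
    """Open a genome FASTA with an on-demand index (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def extract_sequence(model: TranscriptModel, genome: Mapping[str, Sequence]) -> str:
    """Spliced sequence of ``model``, 5'->3' on its own strand.

    ``genome`` may be a pyfaidx Fasta or any scaffold -> string mapping.
    Exons are concatenated in genomic order and the result is
    reverse-complemented for minus-strand models.
    """
    if model.scaffold not in genome:
        raise KeyError(f"{model.id}: scaffold {model.scaffold!r} absent from genome")
    scaffold = genome[model.scaffold]
    if model.interval.end > len(scaffold):
        raise ValueError(
            f"{model.id}: exon out of scaffold bounds "
            f"({model.interval.end} > {len(scaffold)})"
        )
    parts = [str(scaffold[e.start:e.end]) for e in model.exons]
    seq = canonicalize("".join(parts))
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

def _models_from_db(
    db: gffutils.FeatureDB, parent_types: tuple[str, ...], source: str
) -> list[TranscriptModel]:
    models: list[TranscriptModel] = []
    seen: set[str] = set()
    for ftype in parent_types:
        for feat in db.features_of_type(ftype):
            if feat.strand not in VALID_STRANDS:
                logger.warning("%s %s has no strand; record rejected", ftype, feat.id)
                continue
            if feat.id in seen:
                raise ValueError(f"duplicate feature ID {feat.id!r}")
            seen.add(feat.id)
            exon_feats = []
            for child in db.children(feat, featuretype="exon"):
                exon_feats.append(child)
            # descend through mRNA children if exons hang off them
            if not exon_feats:
                for mrna in db.children(feat, featuretype=("mRNA", "transcript")):
                    exon_feats.extend(db.children(mrna, featuretype="exon"))
            if exon_feats:
                exons = [
                    GenomicInterval(feat.seqid, c.start - 1, c.end, feat.strand)
                    for c in exon_feats
                ]
            else:
                exons = [GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)]
            exons.sort(key=lambda e: e.start)
            interval = GenomicInterval(
                feat.seqid, exons[0].start, exons[-1].end, feat.strand
            )
            models.append(TranscriptModel(feat.id, interval, exons, source=source))
    return models


def _has_feature_lines(path: str | Path) -> bool:
    with open(path) as fh:
        return any(line.strip() and not line.startswith("#") for line in fh)


def read_gff3_genes(path: str | Path) -> list[TranscriptModel]:
    """Read predicted gene models from a GFF3 file.

    One :class:`TranscriptModel` per ``gene`` feature (source
    ``predicted_gene``). Genes without exon children get a single exon equal
    to their span. Unstranded genes are rejected with a logged warning;
    duplicate IDs are a hard error.
    """
    if not _has_feature_lines(path):
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    return _models_from_db(db, ("gene",), SOURCE_GENE)


def read_gtf_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read assembled transcript models from a (stranded) GTF file.

    Exon features are grouped by their ``transcript_id`` attribute; exons
    given out of order are sorted by start. Disagreeing exon strands within
    one transcript are a hard error.
    """
    if not _has_feature_lines(path):
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        grouped.setdefault(tid, []).append(feat)
    models = []
    for tid, feats in grouped.items():
        strands = {f.strand for f in feats}
        if len(strands) > 1:
            raise ValueError(f"{tid}: exon strands disagree: {sorted(strands)}")
        strand = strands.pop()
        if strand not in VALID_STRANDS:
            logger.warning("transcript %s has no strand; record rejected", tid)
            continue
        scaffolds = {f.seqid for f in feats}
        if len(scaffolds) > 1:
            raise ValueError(f"{tid}: exons on multiple scaffolds")
        exons = sorted(
            (GenomicInterval(f.seqid, f.start - 1, f.end, strand) for f in feats),
            key=lambda e: e.start,
        )
        interval = GenomicInterval(exons[0].scaffold, exons[0].start, exons[-1].end, strand)
        models.append(TranscriptModel(tid, interval, exons, source=SOURCE_ASSEMBLED))
    models.sort(key=lambda m: (m.scaffold, m.interval.start, m.id))
    return models


def write_gff3_genes(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write gene models back out as GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            iv = m.interval
            fh.write(
                f"{iv.scaffold}\tnatseek\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={m.id}\n"
            )
            for k, e in enumerate(m.exons, 1):
                fh.write(
                    f"{e.scaffold}\tnatseek\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tID={m.id}.exon{k};Parent={m.id}\n"
                )


def write_gtf_transcripts(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF exon lines."""
    with open(path, "w") as fh:
        for m in models:
            for e in m.exons:
                attrs = f'gene_id "{m.id}"; transcript_id "{m.id}";'
                fh.write(
                    f"{e.scaffold}\tnatseek\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def write_fasta(scaffolds: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in scaffolds.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, unit: str = "RPKM") -> ExpressionMatrix:
    """Read a transcript x stage TSV into an :class:`ExpressionMatrix`.

    First column holds transcript ids; the header row names the stages.
    Missing cells, negative values, and duplicated rows are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), unit=unit)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6g")


def read_evidence_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (id, value) evidence TSV with a header line."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: evidence table needs (id, value) columns")
    out: dict[str, float] = {}
    for tid, value in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)):
        if math.isnan(value):
            raise ValueError(f"{path}: missing value for {tid}")
        out[tid] = value
    return out


def write_evidence_table(table: Mapping[str, float], path: str | Path,
                         value_name: str = "value") -> None:
    with open(path, "w") as fh:
        fh.write(f"transcript_id\t{value_name}\n")
        for tid, value in table.items():
            fh.write(f"{tid}\t{value:g}\n")


EVIDENCE_FILES = {
    "nr_best_evalue": "nr.tsv",
    "cpc_score": "cpc.tsv",
    "housekeeping_best_evalue": "housekeeping.tsv",
    "smallrna_best_evalue": "smallrna.tsv",
}


def read_evidence_dir(path: str | Path | None) -> EvidenceTables:
    """Load whichever evidence tables exist under ``path``.

    Missing files simply leave the corresponding table as None (search not
    run); a missing directory yields an entirely empty set.
    """
    tables: dict[str, dict[str, float] | None] = {k: None for k in EVIDENCE_FILES}
    if path is not None:
        path = Path(path)
        for attr, fname in EVIDENCE_FILES.items():
            fpath = path / fname
            if fpath.exists():
                tables[attr] = read_evidence_table(fpath)
    return EvidenceTables(**tables)


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Read a (gene_id, term_id[, term_name]) TSV into gene -> term-set."""
    df = pd.read_csv(path, sep="\t")
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        mapping.setdefault(gene, set()).add(term)
    return mapping


def write_bed6(records: Iterable[tuple[str, int, int, str, int, str]], path: str | Path) -> None:
    """Write (scaffold, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for scaffold, start, end, name, score, strand in records:
            fh.write(f"{scaffold}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
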