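"""Reading and writing MMETSP-style transcriptome bundles.

Each transcriptome assembled by the Marine Microbial Eukaryote
Transcriptome Sequencing Project (MMETSP) ships as a small directory of
flat files: assembled nucleotide sequences (``Nt.fa``), predicted
peptides (``pep.fa``), a Swiss-Prot annotation table
(``swissprot.gff3``), a per-contig read-count table (``contig.dat``),
coding-region calls (``cds.dat``) and assembly statistics
(``stats.txt``).  This module reads and writes that layout, plus the
tab-separated matrix outputs of the mining pipeline.

The original ``contig.dat`` column layout is not documented anywhere
authoritative, so this package adopts an explicit dialect: a
``#total_read_pairs=N`` sidecar line followed by a header row and one
tab-separated record per transcript (``transcript_id``, ``length_bp``,
``mapped_read_pairs``).  ``cds.dat`` is accepted in a bundle directory
but never consumed.

Annotations are accepted either as a GFF3 dialect (one protein-match
feature per hit, with the Swiss-Prot description percent-encoded in the
``Note`` attribute and the subject accession in ``Name``) or as a plain
TSV with at least ``transcript_id`` and ``description`` columns; the
format is auto-detected from the file present.
"""

from __future__ import annotations

import dataclasses
import logging
import urllib.parse
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

PEPTIDE_FASTA = "pep.fa"
NUCLEOTIDE_FASTA = "Nt.fa"
ANNOTATION_GFF = "swissprot.gff3"
ANNOTATION_TSV = "annotations.tsv"
READCOUNT_TABLE = "contig.dat"
STATS_FILE = "stats.txt"
METADATA_FILE = "metadata.yaml"

#: Standard amino-acid alphabet used throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass
class TranscriptRecord:
    """One assembled transcript: identifier, length and read support.

    ``mapped_read_pairs`` and ``nucleotide_length`` are the two
    transcript-level terms of the FPKM formula; the peptide sequence is
    carried for the clustering stage and may be absent.
    """

    transcript_id: str
    nucleotide_length: int
    mapped_read_pairs: int
    peptide_sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if self.nucleotide_length < 1:
            raise ValueError(
                f"{self.transcript_id}: nucleotide_length must be >= 1, "
                f"got {self.nucleotide_length}"
            )
        if self.mapped_read_pairs < 0:
            raise ValueError(
                f"{self.transcript_id}: mapped_read_pairs must be >= 0, "
                f"got {self.mapped_read_pairs}"
            )


@dataclasses.dataclass
class AnnotationHit:
    """One Swiss-Prot annotation row for a transcript.

    Coordinates are 1-based inclusive as in GFF3; they are carried
    verbatim but unused by the mining logic, which works on the
    free-text ``description`` only.
    """

    transcript_id: str
    subject_accession: str
    description: str
    start: int = 1
    end: int = 1
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.description:
            raise ValueError(f"{self.transcript_id}: empty annotation description")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.transcript_id}: invalid coordinates "
                f"start={self.start} end={self.end}"
            )


@dataclasses.dataclass
class AssemblyStats:
    """Assembly summary: sequence count, length extremes and N50."""

    n_sequences: int
    min_length: int
    max_length: int
    n50: int


@dataclasses.dataclass
class TranscriptomeBundle:
    """One transcriptome's sequences, annotations, counts and metadata."""

    mmetsp_code: str
    species: str
    genus: str
    transcripts: list[TranscriptRecord]
    annotations: list[AnnotationHit]
    total_read_pairs: int
    strain: str | None = None
    growth_metadata: dict = dataclasses.field(default_factory=dict)
    n_dropped_annotations: int = 0

    def __post_init__(self) -> None:
        if self.total_read_pairs < 0:
            raise ValueError(f"{self.mmetsp_code}: total_read_pairs must be >= 0")
        ids = [t.transcript_id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"{self.mmetsp_code}: duplicate transcript id {dup!r}")
        known = set(ids)
        unknown = [a.transcript_id for a in self.annotations if a.transcript_id not in known]
        if unknown:
            raise ValueError(
                f"{self.mmetsp_code}: annotations reference unknown transcript "
                f"ids: {sorted(set(unknown))[:5]}"
            )

    @property
    def transcript_index(self) -> dict[str, TranscriptRecord]:
        return {t.transcript_id: t for t in self.transcripts}

    def assembly_stats(self) -> AssemblyStats:
        return compute_assembly_stats([t.nucleotide_length for t in self.transcripts])


def compute_assembly_stats(lengths: Iterable[int]) -> AssemblyStats:
    """Classical assembly statistics for a list of contig lengths in bp.

    N50 is the contig length at which the cumulative sum of lengths,
    taken from the longest contig downwards, first reaches half the
    total assembly length.
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty assembly")
    if (arr < 1).any():
        raise ValueError("all contig lengths must be >= 1")
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half, side="left"))
    return AssemblyStats(
        n_sequences=int(arr.size),
        min_length=int(arr.min()),
        max_length=int(arr.max()),
        n50=int(desc[idx]),
    )


# ---------------------------------------------------------------------------
# Annotation table dialects


_GFF_SAFE = " ()[]+./:'-"  # characters left readable in Note=


def _write_gff3(hits: Sequence[AnnotationHit], path: Path) -> None:
    lines = ["##gff-version 3"]
    for h in hits:
        score = "." if h.score is None else format(h.score, "g")
        note = urllib.parse.quote(h.description, safe=_GFF_SAFE)
        lines.append(
            "\t".join(
                [
                    h.transcript_id,
                    "swissprot",
                    "protein_match",
                    str(h.start),
                    str(h.end),
                    score,
                    "+",
                    ".",
                    f"Name={h.subject_accession};Note={note}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _read_gff3(path: Path) -> list[AnnotationHit]:
    hits = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path.name}: line {ln}: expected 9 GFF3 columns")
        seqid, _source, _ftype, start, end, score, _strand, _phase, attrs = parts
        fields = {}
        for item in attrs.split(";"):
            if item and "=" in item:
                key, _, value = item.partition("=")
                fields[key] = value
        try:
            hits.append(
                AnnotationHit(
                    transcript_id=seqid,
                    subject_accession=fields.get("Name", ""),
                    description=urllib.parse.unquote(fields.get("Note", "")),
                    start=int(start),
                    end=int(end),
                    score=None if score == "." else float(score),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path.name}: line {ln}: {exc}") from exc
    return hits


def _read_annotation_tsv(path: Path) -> list[AnnotationHit]:
    """Plain annotation dialect: transcript_id, description[, accession]."""
    hits = []
    lines = path.read_text().splitlines()
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if ln == 1 and line.split("\t")[0] == "transcript_id":
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path.name}: line {ln}: expected >= 2 columns")
        acc = parts[2] if len(parts) > 2 else ""
        hits.append(
            AnnotationHit(transcript_id=parts[0], subject_accession=acc, description=parts[1])
        )
    return hits


# ---------------------------------------------------------------------------
# Bundle reading / writing


def _read_contig_table(path: Path) -> tuple[list[tuple[str, int, int]], int]:
    rows: list[tuple[str, int, int]] = []
    total: int | None = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#total_read_pairs="):
            total = int(line.partition("=")[2])
            continue
        if line.startswith("transcript_id"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path.name}: line {ln}: expected 3 columns")
        try:
            length = int(parts[1])
            count = int(parts[2])
        except ValueError:
            raise ValueError(
                f"{path.name}: line {ln}: non-integer length or read count"
            ) from None
        if count < 0:
            raise ValueError(f"{path.name}: line {ln}: negative mapped_read_pairs")
        rows.append((parts[0], length, count))
    if total is None:
        raise ValueError(f"{path.name}: missing '#total_read_pairs=' sidecar line")
    return rows, total


def _read_fasta(path: Path) -> dict[str, str]:
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ValueError(f"{path.name}: line 1: not a FASTA record")
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_bundle(directory: str | Path) -> TranscriptomeBundle:
    """Load a bundle directory into a cross-linked :class:`TranscriptomeBundle`.

    Requires at minimum the peptide FASTA, the read-count table, a
    metadata sidecar and an annotation table (GFF3 or TSV).  Annotation
    rows referencing unknown transcript ids are dropped with a logged
    warning; their count is kept on ``n_dropped_annotations``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"bundle directory not found: {directory}")
    for fname in (PEPTIDE_FASTA, READCOUNT_TABLE, METADATA_FILE):
        if not (directory / fname).exists():
            raise FileNotFoundError(f"{directory}: missing mandatory file {fname}")
    gff = directory / ANNOTATION_GFF
    tsv = directory / ANNOTATION_TSV
    if gff.exists():
        raw_hits = _read_gff3(gff)
    elif tsv.exists():
        raw_hits = _read_annotation_tsv(tsv)
    else:
        raise FileNotFoundError(
            f"{directory}: missing mandatory file {ANNOTATION_GFF} (or {ANNOTATION_TSV})"
        )

    meta = yaml.safe_load((directory / METADATA_FILE).read_text()) or {}
    rows, total = _read_contig_table(directory / READCOUNT_TABLE)
    peptides = _read_fasta(directory / PEPTIDE_FASTA)

    known = {tid for tid, _, _ in rows}
    orphan_peps = set(peptides) - known
    if orphan_peps:
        log.warning(
            "%s: %d peptide records without read-count rows ignored",
            directory.name,
            len(orphan_peps),
        )
    transcripts = [
        TranscriptRecord(tid, length, count, peptides.get(tid))
        for tid, length, count in rows
    ]
    hits = [h for h in raw_hits if h.transcript_id in known]
    n_dropped = len(raw_hits) - len(hits)
    if n_dropped:
        log.warning(
            "%s: dropped %d annotation rows referencing unknown transcript ids",
            directory.name,
            n_dropped,
        )
    return TranscriptomeBundle(
        mmetsp_code=str(meta.get("mmetsp_code", directory.name)),
        species=str(meta.get("species", "")),
        genus=str(meta.get("genus", "")),
        strain=meta.get("strain"),
        transcripts=transcripts,
        annotations=hits,
        total_read_pairs=total,
        growth_metadata=dict(meta.get("growth_metadata") or {}),
        n_dropped_annotations=n_dropped,
    )


def write_bundle(bundle: TranscriptomeBundle, directory: str | Path) -> Path:
    """Write a bundle as an MMETSP-style directory; inverse of :func:`read_bundle`.

    Nucleotide sequences are not modelled (only their lengths are), so
    ``Nt.fa`` is written as runs of ``N`` of the recorded length purely
    to keep the file set complete.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pep_records = [
        SeqRecord(Seq(t.peptide_sequence), id=t.transcript_id, description="")
        for t in bundle.transcripts
        if t.peptide_sequence
    ]
    SeqIO.write(pep_records, directory / PEPTIDE_FASTA, "fasta")
    nt_records = [
        SeqRecord(Seq("N" * t.nucleotide_length), id=t.transcript_id, description="")
        for t in bundle.transcripts
    ]
    SeqIO.write(nt_records, directory / NUCLEOTIDE_FASTA, "fasta")
    _write_gff3(bundle.annotations, directory / ANNOTATION_GFF)

    lines = [f"#total_read_pairs={bundle.total_read_pairs}"]
    lines.append("transcript_id\tlength_bp\tmapped_read_pairs")
    for t in bundle.transcripts:
        lines.append(f"{t.transcript_id}\t{t.nucleotide_length}\t{t.mapped_read_pairs}")
    (directory / READCOUNT_TABLE).write_text("\n".join(lines) + "\n")

    if bundle.transcripts:
        stats = bundle.assembly_stats()
        (directory / STATS_FILE).write_text(
            f"n_sequences\t{stats.n_sequences}\n"
            f"min_length\t{stats.min_length}\n"
            f"max_length\t{stats.max_length}\n"
            f"n50\t{stats.n50}\n"
        )

    meta = {
        "mmetsp_code": bundle.mmetsp_code,
        "species": bundle.species,
        "genus": bundle.genus,
        "strain": bundle.strain,
        "growth_metadata": bundle.growth_metadata,
    }
    (directory / METADATA_FILE).write_text(yaml.safe_dump(meta, sort_keys=True))
    return directory


# ---------------------------------------------------------------------------
# Matrix plumbing


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Write a labelled 2-D table as TSV; exact inverse of :func:`read_matrix`."""
    path = Path(path)
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("row and column labels must be unique")
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "id")
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
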