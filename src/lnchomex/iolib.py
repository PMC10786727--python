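"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  BED passes through unchanged;
GTF-lite (1-based closed) is converted on read and restored on write.
Sequences are stored in the DNA alphabet: U is normalised to T on read.
Readers reject malformed input rather than coercing; every writer produces
output that re-reads to an equal value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError
from .motifs import Pwm

PathLike = Union[str, Path]

_VALID_BASES = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript with the attributes the curation filter needs."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    length_nt: int
    fpkm: float
    coding_potential: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"{self.transcript_id}: start >= end")
        if self.length_nt < 1:
            raise FormatError(f"{self.transcript_id}: length_nt < 1")
        if not 0.0 <= self.coding_potential <= 1.0:
            raise FormatError(f"{self.transcript_id}: coding_potential outside [0,1]")
        if self.fpkm < 0:
            raise FormatError(f"{self.transcript_id}: negative fpkm")
        if self.strand not in "+-":
            raise FormatError(f"{self.transcript_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicAnchor:
    """A one-to-one corresponding genomic segment pair between two assemblies."""

    anchor_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if self.start_a >= self.end_a or self.start_b >= self.end_b:
            raise FormatError(f"anchor {self.anchor_id}: start >= end")
        if min(self.start_a, self.start_b) < 0:
            raise FormatError(f"anchor {self.anchor_id}: negative coordinate")


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    evidence: str  # "protein" or "anchor"

    def __post_init__(self) -> None:
        if self.evidence not in ("protein", "anchor"):
            raise FormatError(f"unknown evidence class {self.evidence!r}")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative coordinate in interval {self.name}")
        if self.start >= self.end:
            raise FormatError(f"start >= end in interval {self.name}")


@dataclass(frozen=True)
class GtfFeature:
    """One GTF-lite row, converted to 0-based half-open on read."""

    seqname: str
    source: str
    feature: str
    start: int
    end: int
    score: str
    strand: str
    frame: str
    gene_id: str
    transcript_id: str


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read FASTA into {id: uppercase DNA sequence}; U becomes T."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(f"invalid characters {sorted(bad)} in {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_motifs(path: PathLike, species: str = "") -> List[Pwm]:
    """Parse a MEME minimal motif file into regularised PWMs.

    Raw letter-probability rows must sum to 1 within 0.01; they are then
    blended with the background (pseudocount regularisation) so every row sums
    to 1 within 1e-6 and no cell is zero.  The MOTIF line's alternate name, if
    present, is taken as the RBP name.
    """
    from .motifs import regularize_matrix

    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines()]
    if not any(ln.startswith("MEME version") for ln in lines):
        raise FormatError("missing 'MEME version' line")
    background = np.full(4, 0.25)
    alphabet = None
    i = 0
    pwms: List[Pwm] = []
    seen = set()
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("ALPHABET"):
            alphabet = ln.split("=", 1)[1].strip() if "=" in ln else ln.split()[-1]
            if alphabet not in ("ACGT", "ACGU"):
                raise FormatError(f"unknown alphabet {alphabet!r}")
        elif ln.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[k]: float(parts[k + 1]) for k in range(0, len(parts), 2)}
            background = np.array([freq.get(b, freq.get({"T": "U"}.get(b, b), 0.25))
                                   for b in "ACGT"])
        elif ln.startswith("MOTIF"):
            fields = ln.split()
            motif_id = fields[1]
            rbp_name = fields[2] if len(fields) > 2 else motif_id
            if motif_id in seen:
                raise FormatError(f"duplicate motif id {motif_id!r}")
            seen.add(motif_id)
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"motif {motif_id!r} has no matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"motif {motif_id!r} has no matrix")
            header = dict(
                zip(*(iter(lines[i].split("matrix:", 1)[1].replace("=", " ").split()),) * 2)
            )
            w = int(header.get("w", 0))
            if w < 1:
                raise FormatError(f"motif {motif_id!r}: missing width")
            rows = []
            for k in range(w):
                i += 1
                vals = [float(v) for v in lines[i].split()]
                if len(vals) != 4:
                    raise FormatError(f"motif {motif_id!r}: row {k} has {len(vals)} columns")
                if abs(sum(vals) - 1.0) > 0.01:
                    raise FormatError(
                        f"motif {motif_id!r}: row {k} sums to {sum(vals):.4f}"
                    )
                rows.append(vals)
            matrix = regularize_matrix(np.array(rows), background, 1e-3)
            pwms.append(Pwm(motif_id, rbp_name, species, matrix, background))
        i += 1
    return pwms


def write_meme_motifs(pwms: Sequence[Pwm], path: PathLike) -> None:
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\n")
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    buf.write("Background letter frequencies\n")
    buf.write(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate("ACGT")) + "\n\n")
    for p in pwms:
        buf.write(f"MOTIF {p.motif_id} {p.rbp_name}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {p.width} nsites= 20 E= 0\n")
        for row in p.matrix:
            buf.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# BED and GTF-lite


def read_bed(path: PathLike) -> List[Interval]:
    """Read BED3-BED6 (0-based half-open, unchanged internally)."""
    out: List[Interval] = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t")
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        out.append(
            Interval(
                f[0], start, end,
                f[3] if len(f) > 3 else ".",
                float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                f[5] if len(f) > 5 else ".",
            )
        )
    return out


def write_bed(intervals: Sequence[Interval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


read_intervals = read_bed


def _parse_gtf_attributes(attr: str) -> Dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: PathLike) -> List[GtfFeature]:
    """Read GTF-lite; 1-based closed coordinates are converted to 0-based half-open."""
    out: List[GtfFeature] = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 GTF columns, got {len(f)}")
        try:
            start1, end1 = int(f[3]), int(f[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start1 < 1 or end1 < start1:
            raise FormatError(f"{path}:{lineno}: bad GTF coordinates {start1}-{end1}")
        attrs = _parse_gtf_attributes(f[8])
        if "gene_id" not in attrs:
            raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
        out.append(
            GtfFeature(f[0], f[1], f[2], start1 - 1, end1, f[5], f[6], f[7],
                       attrs["gene_id"], attrs.get("transcript_id", ""))
        )
    return out


def write_gtf(features: Sequence[GtfFeature], path: PathLike) -> None:
    with open(path, "w") as fh:
        for ft in features:
            attrs = f'gene_id "{ft.gene_id}";'
            if ft.transcript_id:
                attrs += f' transcript_id "{ft.transcript_id}";'
            fh.write(
                "\t".join(
                    [ft.seqname, ft.source, ft.feature, str(ft.start + 1), str(ft.end),
                     ft.score, ft.strand, ft.frame, attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# typed TSV tables

TABLE_SCHEMAS: Dict[str, Dict[str, type]] = {
    "anchors": {
        "anchor_id": str, "chrom_a": str, "start_a": int, "end_a": int,
        "chrom_b": str, "start_b": int, "end_b": int,
    },
    "homolog_pairs": {"gene_a": str, "gene_b": str, "evidence": str},
    "variants": {"position": int, "allele_frequency": float},
    "transcripts": {
        "transcript_id": str, "gene_id": str, "chrom": str, "strand": str,
        "start": int, "end": int, "biotype": str, "length_nt": int,
        "fpkm": float, "coding_potential": float,
    },
}


def read_table(path: PathLike, schema: str) -> pd.DataFrame:
    """Read a TSV with a header row and validate it against a named schema."""
    if schema not in TABLE_SCHEMAS:
        raise FormatError(f"unknown table schema {schema!r}")
    spec = TABLE_SCHEMAS[schema]
    try:
        df = pd.read_csv(path, sep="\t", dtype={k: v for k, v in spec.items() if v is str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = set(spec) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col, typ in spec.items():
        if typ in (int, float):
            try:
                df[col] = df[col].astype(typ)
            except ValueError as exc:
                raise FormatError(f"{path}: column {col!r} is not {typ.__name__}") from exc
    if schema == "anchors":
        if df["anchor_id"].duplicated().any():
            raise FormatError(f"{path}: duplicated anchor_id (one-to-one violated)")
        if ((df["start_a"] >= df["end_a"]) | (df["start_b"] >= df["end_b"])).any():
            raise FormatError(f"{path}: anchor with start >= end")
        if (df[["start_a", "start_b"]] < 0).any().any():
            raise FormatError(f"{path}: negative coordinate")
    elif schema == "homolog_pairs":
        for _, grp in df.groupby("evidence"):
            if grp["gene_a"].duplicated().any() or grp["gene_b"].duplicated().any():
                raise FormatError(f"{path}: homolog pairs not one-to-one within class")
    elif schema == "variants":
        if ((df["allele_frequency"] < 0) | (df["allele_frequency"] > 1)).any():
            raise FormatError(f"{path}: allele_frequency outside [0,1]")
    return df


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def transcripts_from_table(df: pd.DataFrame) -> List[TranscriptRecord]:
    return [TranscriptRecord(**row) for row in df.to_dict("records")]


# ---------------------------------------------------------------------------
# lncRNA curation filter


def filter_lncrna_candidates(
    records: Sequence[TranscriptRecord],
    min_len: int = 200,
    min_fpkm: float = 0.5,
    max_coding: float = 0.5,
) -> List[TranscriptRecord]:
    """Retain transcripts passing the lncRNA curation thresholds.

    Kept iff length >= min_len (default 200 nt), FPKM strictly > min_fpkm
    (default 0.5) and coding potential <= max_coding (default 0.5; a CPAT
    score above 0.5 marks a transcript as coding and excludes it).
    """
    return [
        r for r in records
        if r.length_nt >= min_len and r.fpkm > min_fpkm and r.coding_potential <= max_coding
    ]
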