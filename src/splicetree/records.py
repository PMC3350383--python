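"""Exon records and splice-site windowing.

An exon is represented together with its immediate intronic context: the
intron sequence 5' of the exon (``up_flank``, ending at the acceptor site)
and 3' of the exon (``down_flank``, starting at the donor site).  All
downstream scorers consume fixed windows cut around the two splice sites;
:func:`cut_windows` is the single place those windows are defined.

A first exon has no upstream intron and a last exon no downstream intron;
the corresponding flank is empty and every window (hence every feature)
depending on it is *missing*, never silently zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq

VALID_LABELS = ("authentic", "cryptic", "unknown")

#: intronic/exonic spans of the splice-site windows (nt)
DONOR_EXONIC, DONOR_INTRONIC = 3, 6            # 9-nt donor window
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3     # 23-nt acceptor window
ACC_SHAPIRO_INTRONIC, ACC_SHAPIRO_EXONIC = 12, 2
FLANK_WINDOW = 70                              # per-side GC / folding span


class RecordError(ValueError):
    """Raised for malformed exon records or annotations."""


def _check_dna(seq: str, what: str, rec_id: str, degenerate: bool) -> None:
    allowed = set("ACGTN" if degenerate else "ACGT")
    bad = set(seq) - allowed
    if bad:
        raise RecordError(
            f"record {rec_id!r}: {what} contains invalid characters {sorted(bad)}"
        )


@dataclass
class ExonRecord:
    """One exon with its intronic flanks and an authenticity label."""

    id: str
    label: str
    exon_seq: str
    up_flank: str = ""
    down_flank: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise RecordError(
                f"record {self.id!r}: unknown label {self.label!r} "
                f"(expected one of {VALID_LABELS})"
            )
        self.exon_seq = self.exon_seq.upper()
        self.up_flank = self.up_flank.upper()
        self.down_flank = self.down_flank.upper()
        if len(self.exon_seq) < 1:
            raise RecordError(f"record {self.id!r}: empty exon sequence")
        _check_dna(self.exon_seq, "exon_seq", self.id, self.degenerate)
        _check_dna(self.up_flank, "up_flank", self.id, self.degenerate)
        _check_dna(self.down_flank, "down_flank", self.id, self.degenerate)

    @property
    def size(self) -> int:
        return len(self.exon_seq)


@dataclass
class SpliceWindows:
    """Fixed sequence windows around the two splice sites of one exon.

    ``None`` marks a window that would extend past the available sequence
    (an absent or too-short flank, or an exon shorter than the exonic part
    of a splice-site window).  The two 140-nt windows tolerate a short
    *exonic* side: they are then built from all available exonic
    nucleotides and flagged truncated rather than dropped.
    """

    donor9: Optional[str] = None
    acceptor23: Optional[str] = None
    donor_shapiro: Optional[str] = None
    acceptor_shapiro: Optional[str] = None
    win5: Optional[str] = None
    win3: Optional[str] = None
    win5_truncated: bool = False
    win3_truncated: bool = False


def cut_windows(rec: ExonRecord) -> SpliceWindows:
    """Cut every scorer window from an :class:`ExonRecord`.

    The donor window spans the last 3 exonic and first 6 intronic nt, the
    acceptor window the last 20 intronic and first 3 exonic nt (12+2 for
    its Shapiro-matrix counterpart).  ``win5``/``win3`` take up to 70 nt on
    each side of the donor/acceptor boundary.
    """
    exon, up, down = rec.exon_seq, rec.up_flank, rec.down_flank
    w = SpliceWindows()

    if len(down) >= DONOR_INTRONIC and len(exon) >= DONOR_EXONIC:
        w.donor9 = exon[-DONOR_EXONIC:] + down[:DONOR_INTRONIC]
        w.donor_shapiro = w.donor9
    if len(up) >= ACCEPTOR_INTRONIC and len(exon) >= ACCEPTOR_EXONIC:
        w.acceptor23 = up[-ACCEPTOR_INTRONIC:] + exon[:ACCEPTOR_EXONIC]
    if len(up) >= ACC_SHAPIRO_INTRONIC and len(exon) >= ACC_SHAPIRO_EXONIC:
        w.acceptor_shapiro = up[-ACC_SHAPIRO_INTRONIC:] + exon[:ACC_SHAPIRO_EXONIC]

    if len(down) >= FLANK_WINDOW:
        exonic = exon[-FLANK_WINDOW:]
        w.win5 = exonic + down[:FLANK_WINDOW]
        w.win5_truncated = len(exonic) < FLANK_WINDOW
    if len(up) >= FLANK_WINDOW:
        exonic = exon[:FLANK_WINDOW]
        w.win3 = up[-FLANK_WINDOW:] + exonic
        w.win3_truncated = len(exonic) < FLANK_WINDOW
    return w


# ---------------------------------------------------------------------------
# annotation + FASTA loading
# ---------------------------------------------------------------------------

@dataclass
class _BedRow:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    name: str
    strand: str
    label: str
    line_no: int


def _parse_bed(annotation_path: Path):
    rows = []
    with open(annotation_path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise RecordError(
                    f"{annotation_path}:{i}: BED row needs >=3 columns, got {len(f)}"
                )
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise RecordError(
                    f"{annotation_path}:{i}: non-integer coordinate"
                ) from exc
            if not 0 <= start < end:
                raise RecordError(
                    f"{annotation_path}:{i}: invalid interval [{start},{end})"
                )
            name = f[3] if len(f) > 3 and f[3] not in (".", "") else f"exon_{i}"
            strand = f[5] if len(f) > 5 else "+"
            if strand not in "+-":
                raise RecordError(f"{annotation_path}:{i}: bad strand {strand!r}")
            label = f[6] if len(f) > 6 and f[6] not in (".", "") else "unknown"
            if label not in VALID_LABELS:
                raise RecordError(
                    f"{annotation_path}:{i}: unknown label {label!r} "
                    f"(expected one of {VALID_LABELS})"
                )
            rows.append(_BedRow(f[0], start, end, name, strand, label, i))
    return rows


def load_exon_records(
    fasta_path, annotation_path, flank_len: int = 70
) -> list[ExonRecord]:
    """Assemble :class:`ExonRecord` objects from a FASTA and a BED table.

    BED coordinates are 0-based half-open; optional columns 4-7 carry
    name, score (ignored), strand and an authenticity label.  Flanks are
    cut from the reference sequence (``flank_len`` nt per side, shorter at
    a contig edge; empty when the exon abuts the sequence boundary).
    Minus-strand exons are reverse-complemented at load time so that all
    downstream computation happens on the sense strand.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be positive")
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise RecordError(f"no FASTA records found in {fasta_path}")

    records = []
    for row in _parse_bed(Path(annotation_path)):
        if row.chrom not in seqs:
            raise RecordError(
                f"{annotation_path}:{row.line_no}: sequence {row.chrom!r} "
                "absent from FASTA"
            )
        ref = seqs[row.chrom]
        if row.end > len(ref):
            raise RecordError(
                f"{annotation_path}:{row.line_no}: interval end {row.end} exceeds "
                f"sequence {row.chrom!r} length {len(ref)}"
            )
        exon = ref[row.start:row.end]
        left = ref[max(0, row.start - flank_len):row.start]
        right = ref[row.end:row.end + flank_len]
        if row.strand == "-":
            exon = str(Seq(exon).reverse_complement())
            left, right = (
                str(Seq(right).reverse_complement()),
                str(Seq(left).reverse_complement()),
            )
        records.append(
            ExonRecord(
                id=row.name,
                label=row.label,
                exon_seq=exon,
                up_flank=left,
                down_flank=right,
                degenerate="N" in exon + left + right,
            )
        )
    return records


# ---------------------------------------------------------------------------
# record TSV exchange format
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("id", "label", "exon_seq", "up_flank", "down_flank")


def write_record_tsv(records, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for r in records:
            w.writerow([r.id, r.label, r.exon_seq, r.up_flank, r.down_flank])


def read_record_tsv(path) -> list[ExonRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise RecordError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            seq = row["exon_seq"] + row["up_flank"] + row["down_flank"]
            records.append(
                ExonRecord(
                    id=row["id"],
                    label=row["label"],
                    exon_seq=row["exon_seq"],
                    up_flank=row["up_flank"],
                    down_flank=row["down_flank"],
                    degenerate="N" in seq.upper(),
                )
            )
    return records
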