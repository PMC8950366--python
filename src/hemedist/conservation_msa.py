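"""MSA conservation analysis and heme-binding-motif scanning.

Given an alignment of CYP homologs with a designated reference sequence,
this module maps a reference residue number (e.g. 445) to its alignment
column, reports how conserved that column is across the homologs together
with the substitution spectrum, and scans ungapped sequences for the
heme-binding motif GX[HR]XC[PLAV]G around the iron-coordinating cysteine.
Position "+2" of the motif — two residues downstream of that Cys — is the
glycine whose substitution tolerance motivates the analysis.

Columns and residue positions are 1-based throughout, matching residue
numbering conventions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO, SeqIO

from .errors import MSAError

GAP = "-"

#: Residues admitted at motif positions 3 and 6.
MOTIF_POS3 = frozenset("HR")
MOTIF_POS6 = frozenset("PLAV")


@dataclass
class MSA:
    """Aligned sequences (``-`` gaps) with a designated reference record."""

    records: list[tuple[str, str]]
    ref_id: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise MSAError("alignment has no records")
        length = len(self.records[0][1])
        for rid, seq in self.records:
            if len(seq) != length:
                raise MSAError(
                    f"record {rid!r} has length {len(seq)}, expected {length} "
                    "(ragged alignment)"
                )
        if self.ref_id is not None and self.ref_id not in {r for r, _ in self.records}:
            raise MSAError(f"reference id {self.ref_id!r} not present in alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def reference(self) -> tuple[str, str]:
        if self.ref_id is None:
            raise MSAError("no reference record designated (set ref_id)")
        for rid, seq in self.records:
            if rid == self.ref_id:
                return rid, seq
        raise MSAError(f"reference id {self.ref_id!r} not present")  # pragma: no cover


@dataclass(frozen=True)
class ConservationReport:
    ref_position: int
    column: int  # 1-based alignment column
    conserved_fraction: float
    conserved_percent: int  # integer-rounded, reporting style
    n_sequences: int  # sequences counted in the denominator
    n_conserved: int
    n_gapped: int
    substitution_counts: dict[str, int]
    count_gaps: bool


@dataclass(frozen=True)
class MotifHit:
    start: int  # 1-based position in the ungapped sequence
    span: str  # the 7-residue match
    cys_pos: int
    plus_two_pos: int


def read_msa(path: str | Path, format: str = "fasta") -> MSA:
    """Read an alignment from aligned FASTA or Clustal format.

    Ragged alignments raise :class:`~hemedist.errors.MSAError` naming the
    offending record. The reference record is designated by the caller
    afterwards (``msa.ref_id = ...``).
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"format must be 'fasta' or 'clustal', got {format!r}")
    path = Path(path)
    try:
        alignment = AlignIO.read(str(path), format)
    except ValueError as exc:
        # Re-scan record-wise to name the offending record on ragged input.
        try:
            records = list(SeqIO.parse(str(path), format))
        except Exception:
            records = []
        if records:
            length = len(records[0].seq)
            for rec in records:
                if len(rec.seq) != length:
                    raise MSAError(
                        f"{path}: record {rec.id!r} has length {len(rec.seq)}, "
                        f"expected {length} (ragged alignment)"
                    ) from exc
        raise MSAError(f"{path}: {exc}") from exc
    if len(alignment) < 2:
        raise MSAError(f"{path}: alignment must contain at least 2 records")
    return MSA(records=[(rec.id, str(rec.seq).upper()) for rec in alignment])


def write_msa(msa: MSA, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment as aligned FASTA (the only output dialect)."""
    if format != "fasta":
        raise ValueError("only FASTA output is supported")
    with open(path, "w") as fh:
        for rid, seq in msa.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def ungap(seq: str) -> str:
    return seq.replace(GAP, "")


def map_position(msa: MSA, ref_position: int) -> int:
    """Alignment column (1-based) holding the reference's ``ref_position``-th
    non-gap residue."""
    if ref_position < 1:
        raise MSAError(f"ref_position must be >= 1, got {ref_position}")
    _, ref_seq = msa.reference()
    count = 0
    for col, ch in enumerate(ref_seq, start=1):
        if ch != GAP:
            count += 1
            if count == ref_position:
                return col
    raise MSAError(
        f"reference has only {count} residues; position {ref_position} is beyond it"
    )


def column_conservation(
    msa: MSA, column: int, count_gaps: bool = False
) -> ConservationReport:
    """Fraction of sequences sharing the reference residue at a column.

    Gap-holding sequences never count as conserved; by default they are also
    excluded from the denominator (``count_gaps=True`` includes them). The
    substitution spectrum over non-reference residues is returned alongside.
    """
    if not (1 <= column <= msa.length):
        raise MSAError(f"column {column} outside alignment (length {msa.length})")
    _, ref_seq = msa.reference()
    ref_char = ref_seq[column - 1]
    if ref_char == GAP:
        raise MSAError(f"reference is gapped at column {column}")
    chars = [seq[column - 1] for _, seq in msa.records]
    n_gapped = sum(1 for c in chars if c == GAP)
    n_conserved = sum(1 for c in chars if c == ref_char)
    substitutions = Counter(c for c in chars if c not in (ref_char, GAP))
    denominator = len(chars) if count_gaps else len(chars) - n_gapped
    if denominator == 0:
        raise MSAError(f"column {column}: no ungapped observations")
    fraction = n_conserved / denominator
    # Reverse-map the column to the reference residue number for reporting.
    ref_position = sum(1 for c in ref_seq[:column] if c != GAP)
    return ConservationReport(
        ref_position=ref_position,
        column=column,
        conserved_fraction=fraction,
        conserved_percent=int(round(100.0 * fraction)),
        n_sequences=denominator,
        n_conserved=n_conserved,
        n_gapped=n_gapped,
        substitution_counts=dict(substitutions),
        count_gaps=count_gaps,
    )


def _window_matches(window: str, plus_two_allowed: frozenset[str]) -> bool:
    return (
        window[0] == "G"
        and window[2] in MOTIF_POS3
        and window[4] == "C"
        and window[5] in MOTIF_POS6
        and window[6] in plus_two_allowed
    )


def scan_heme_motif(seq: str) -> list[MotifHit]:
    """All (possibly overlapping) matches of GX[HR]XC[PLAV]G in an ungapped
    sequence, each annotated with the Cys position and the +2 position."""
    return relaxed_motif_scan(seq, allowed_plus_two=set())


def relaxed_motif_scan(seq: str, allowed_plus_two: set[str]) -> list[MotifHit]:
    """Motif scan admitting extra residues at position +2 (the terminal G).

    Crystallographic surveys report Ala, Ser or Lys substituting the +2 Gly
    in functional heme proteins; pass ``{"A", "S", "K"}`` to admit those. An
    empty set falls back to the strict scan.
    """
    if GAP in seq:
        raise ValueError("motif scan requires an ungapped sequence")
    seq = seq.upper()
    plus_two = frozenset({"G"} | set(allowed_plus_two))
    hits = []
    for start in range(len(seq) - 6):
        window = seq[start : start + 7]
        if _window_matches(window, plus_two):
            hits.append(
                MotifHit(
                    start=start + 1,
                    span=window,
                    cys_pos=start + 5,
                    plus_two_pos=start + 7,
                )
            )
    return hits
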