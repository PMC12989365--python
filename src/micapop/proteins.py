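"""Reference-anchored protein variation analysis.

Sequences are each globally aligned to a reference protein and the pairwise
alignments are merged on reference coordinates (star alignment), which keeps
mature-protein numbering exact: position 1 is the first residue of the
mature protein (encoded by the first codon of exon 2). Insertion columns
relative to the reference are tagged separately and never shift numbering.

Also provided: per-allele difference calls against the reference, the
Met/Val classification at mature position 129, frameshift / premature-stop
null-allele detection on coding sequences, and nearest-frequent-allele
grouping.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "Column",
    "GroupAssignment",
    "NullCall",
    "ProteinAlignment",
    "Variant",
    "build_alignment",
    "classify_aa129",
    "detect_null",
    "group_by_nearest_frequent",
    "variant_matrix",
]

GAP = "-"
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
_NT_ALPHABET = set("ACGT")

# integer scoring constants for the star alignment (documented convention)
GAP_OPEN = -10
GAP_EXTEND = -1


class Column(NamedTuple):
    """Alignment column in mature-protein coordinates.

    ``insertion_index`` 0 marks the reference column at ``position``;
    ``insertion_index`` k>0 marks the k-th inserted column after it
    (``position`` 0 holds insertions before the first residue).
    """

    position: int
    insertion_index: int = 0

    @property
    def is_insertion(self) -> bool:
        return self.insertion_index > 0


@dataclass
class ProteinAlignment:
    reference_id: str
    columns: list[Column]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        width = len(self.columns)
        for name, row in self.rows.items():
            if len(row) != width:
                raise ValueError(
                    f"row {name!r} has length {len(row)}, expected {width}"
                )

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_id]

    def column_index(self, position: int, insertion_index: int = 0) -> int:
        try:
            return self.columns.index(Column(position, insertion_index))
        except ValueError:
            raise KeyError(
                f"no alignment column at mature position {position}"
            ) from None

    def symbol_at(self, allele: str, position: int) -> str:
        return self.rows[allele][self.column_index(position)]


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def build_alignment(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    reference_id: str,
) -> ProteinAlignment:
    """Star-align amino-acid sequences against the reference.

    Each sequence is globally aligned to the reference (BLOSUM62,
    affine gaps open 10 / extend 1) and the pairwise alignments are merged
    on reference coordinates; insertion columns are tagged per reference
    position.
    """
    seqs = dict(sequences)
    if reference_id not in seqs:
        raise ValueError(f"reference {reference_id!r} missing from input")
    for name, seq in seqs.items():
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {name!r} contains non-amino-acid symbols: {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"sequence {name!r} is empty")

    ref = seqs[reference_id]
    aligner = _protein_aligner()

    per_seq_pos: dict[str, dict[int, str]] = {}
    per_seq_ins: dict[str, dict[int, str]] = {}
    for name, seq in seqs.items():
        if name == reference_id:
            per_seq_pos[name] = {i + 1: ref[i] for i in range(len(ref))}
            per_seq_ins[name] = {}
            continue
        aln = aligner.align(ref, seq)[0]
        ref_aln, seq_aln = str(aln[0]), str(aln[1])
        pos_map: dict[int, str] = {}
        ins_map: dict[int, str] = defaultdict(str)
        pos = 0
        for r, s in zip(ref_aln, seq_aln):
            if r == GAP:
                ins_map[pos] += s
            else:
                pos += 1
                pos_map[pos] = s
        per_seq_pos[name] = pos_map
        per_seq_ins[name] = dict(ins_map)

    ins_width: dict[int, int] = defaultdict(int)
    for ins_map in per_seq_ins.values():
        for pos, inserted in ins_map.items():
            ins_width[pos] = max(ins_width[pos], len(inserted))

    columns: list[Column] = []
    for pos in range(0, len(ref) + 1):
        if pos > 0:
            columns.append(Column(pos, 0))
        for k in range(1, ins_width.get(pos, 0) + 1):
            columns.append(Column(pos, k))

    rows: dict[str, str] = {}
    for name in seqs:
        pos_map = per_seq_pos[name]
        ins_map = per_seq_ins.get(name, {})
        symbols = []
        for col in columns:
            if col.insertion_index == 0:
                symbols.append(pos_map.get(col.position, GAP))
            else:
                inserted = ins_map.get(col.position, "")
                symbols.append(
                    inserted[col.insertion_index - 1]
                    if col.insertion_index <= len(inserted)
                    else GAP
                )
        rows[name] = "".join(symbols)

    return ProteinAlignment(reference_id=reference_id, columns=columns, rows=rows)


class Variant(NamedTuple):
    position: int
    insertion_index: int
    ref_symbol: str
    alt_symbol: str


@dataclass
class VariantMatrix:
    reference_id: str
    variants: dict[str, list[Variant]]

    @property
    def summary(self) -> dict[str, int]:
        return {a: len(v) for a, v in self.variants.items()}


def variant_matrix(aln: ProteinAlignment) -> VariantMatrix:
    """All columns where an allele differs from the reference.

    Gap-vs-residue counts as a difference (reported with the gap symbol);
    gap-vs-gap does not.
    """
    ref_row = aln.reference_row
    variants: dict[str, list[Variant]] = {}
    for name, row in aln.rows.items():
        diffs = [
            Variant(col.position, col.insertion_index, r, s)
            for col, r, s in zip(aln.columns, ref_row, row)
            if r != s
        ]
        variants[name] = diffs
    return VariantMatrix(reference_id=aln.reference_id, variants=variants)


AA129_POSITION = 129


def classify_aa129(aln: ProteinAlignment) -> dict[str, str]:
    """Met/Val dimorphism at mature position 129; anything else is 'other'."""
    idx = aln.column_index(AA129_POSITION)
    out = {}
    for name, row in aln.rows.items():
        symbol = row[idx]
        out[name] = {"M": "Met", "V": "Val"}.get(symbol, "other")
    return out


class NullCall(NamedTuple):
    is_null: bool
    mechanism: str  # "frameshift" | "premature_stop" | "none"
    exon: int | None


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -2
    return aligner


def _exon_of(
    ref_pos: int,
    exon_boundaries: Sequence[tuple[int, int]],
    exon_numbers: Sequence[int],
) -> int | None:
    for (start, end), number in zip(exon_boundaries, exon_numbers):
        if start <= ref_pos < end:
            return number
    return None


def detect_null(
    cds: str,
    reference_cds: str,
    exon_boundaries: Sequence[tuple[int, int]],
    exon_numbers: Sequence[int] | None = None,
) -> NullCall:
    """Detect loss-of-function variants in a coding sequence.

    ``exon_boundaries`` are half-open 0-based intervals on the reference CDS;
    ``exon_numbers`` give their labels (default 1..len). An indel whose
    length is not a multiple of 3 is a frameshift (the 5'-most one wins and
    its exon is reported). Otherwise the query is translated with the
    standard nuclear code and an in-frame stop before the final codon is a
    premature stop.
    """
    if not cds:
        raise ValueError("empty coding sequence")
    for name, seq in (("query", cds), ("reference", reference_cds)):
        bad = set(seq.upper()) - _NT_ALPHABET
        if bad:
            raise ValueError(f"{name} CDS contains non-ACGT symbols: {sorted(bad)}")
    cds = cds.upper()
    reference_cds = reference_cds.upper()
    if exon_numbers is None:
        exon_numbers = list(range(1, len(exon_boundaries) + 1))

    aln = _nt_aligner().align(reference_cds, cds)[0]
    ref_aln, qry_aln = str(aln[0]), str(aln[1])

    # collect gap runs in either row, tracking position on the reference
    runs: list[tuple[int, int]] = []  # (ref position of run start, run length)
    query_to_ref: dict[int, int] = {}  # query nt index -> ref nt index
    ref_pos = qry_pos = 0
    cur_row: str | None = None
    cur_len = cur_start = 0
    for r, q in zip(ref_aln, qry_aln):
        gap_row = "ref" if r == GAP else "qry" if q == GAP else None
        if gap_row != cur_row:
            if cur_row is not None:
                runs.append((cur_start, cur_len))
            cur_row, cur_len, cur_start = gap_row, 0, ref_pos
        if gap_row is not None:
            cur_len += 1
        if r != GAP:
            ref_pos += 1
        if q != GAP:
            query_to_ref[qry_pos] = max(ref_pos - 1, 0)
            qry_pos += 1
    if cur_row is not None:
        runs.append((cur_start, cur_len))

    for start, length in runs:
        if length % 3 != 0:
            exon = _exon_of(
                min(start, len(reference_cds) - 1), exon_boundaries, exon_numbers
            )
            return NullCall(is_null=True, mechanism="frameshift", exon=exon)

    protein = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop_idx = protein.find("*")
    if stop_idx != -1 and stop_idx < len(protein) - 1:
        stop_nt = stop_idx * 3
        ref_nt = query_to_ref.get(stop_nt, stop_nt)
        exon = _exon_of(ref_nt, exon_boundaries, exon_numbers)
        return NullCall(is_null=True, mechanism="premature_stop", exon=exon)
    return NullCall(is_null=False, mechanism="none", exon=None)


class GroupAssignment(NamedTuple):
    label: str
    distance: int
    tie: bool


def group_by_nearest_frequent(
    aln: ProteinAlignment, frequent: Sequence[str]
) -> dict[str, GroupAssignment]:
    """Assign every allele to the closest of the given frequent alleles.

    Distance is the column-wise symbol difference (gap-vs-gap equal) on the
    merged alignment rows; ties go to the lexicographically smallest frequent
    allele and are flagged.
    """
    if not frequent:
        raise ValueError("empty list of frequent alleles")
    missing = [f for f in frequent if f not in aln.rows]
    if missing:
        raise ValueError(f"frequent alleles absent from alignment: {missing}")

    anchors = sorted(frequent)
    out = {}
    for name, row in aln.rows.items():
        distances = {
            f: sum(1 for a, b in zip(row, aln.rows[f]) if a != b) for f in anchors
        }
        best = min(distances.values())
        winners = [f for f in anchors if distances[f] == best]
        out[name] = GroupAssignment(
            label=winners[0], distance=best, tie=len(winners) > 1
        )
    return out
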