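"""Tessellation-based repeat detection and annotation.

A query fragment of the period length is placed greedily (non-overlapping,
best score first) on a target chain; each accepted placement becomes a
repeat unit whose residues are assigned canonical positions 1..period from
the structural equivalences. Target residues inside a unit that align to no
query position are insertions; query positions with no target partner are
deletions. Units are classified N-terminal / internal / C-terminal by
position in the array.

The per-unit pairwise alignments are merged into a single multiple sequence
alignment over the canonical frame: the global column set is the union of
the query positions and, after every query position, an insertion block
wide enough for the longest insertion observed there in any unit. Gap
redistribution keeps two guarantees: every gap introduced into a query row
is mirrored in its paired target row (so all query rows stay identical),
and removing the gaps from any target row returns exactly its source
subsequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignkernel import AlignParams, StructuralAlignment, align_fragment
from .structmodel import Fragment, StructureModel

log = logging.getLogger(__name__)

N_TERMINAL, INTERNAL, C_TERMINAL = "N_TERMINAL", "INTERNAL", "C_TERMINAL"
INSERTION, DELETION = "INSERTION", "DELETION"


@dataclass
class RepeatUnit:
    start: int  # 0-based half-open on the target chain
    end: int
    klass: Optional[str] = None
    canonical_map: dict = field(default_factory=dict)  # target idx -> 1..p
    alignment: Optional[StructuralAlignment] = None
    trailing_insertion: int = 0  # unaligned residues attached after this unit

    def canonical_of(self, target_index: int) -> Optional[int]:
        return self.canonical_map.get(target_index)

    def insertion_indices(self) -> list:
        return [i for i in range(self.start, self.end)
                if i not in self.canonical_map]


@dataclass
class RepeatArray:
    target_id: str
    chain_id: str
    units: list  # of RepeatUnit, ordered, non-overlapping
    query_id: str
    period: int

    def __len__(self) -> int:
        return len(self.units)

    def unit_of(self, target_index: int) -> Optional[int]:
        for k, u in enumerate(self.units):
            if u.start <= target_index < u.end:
                return k
        return None


@dataclass(frozen=True)
class IndelAnnotation:
    kind: str  # INSERTION | DELETION
    canonical_position: int  # 1..period; insertion sits after this position
    length: int
    unit_index: int
    target_id: str = ""


def detect_repeats(
    target: StructureModel,
    chain_id: str,
    query: Fragment,
    period: int,
    params: Optional[AlignParams] = None,
) -> RepeatArray:
    """Greedy non-overlapping placements of the query on the target chain."""
    if query.length != period:
        raise ValueError("query length must equal the period")
    params = params or AlignParams()
    params = AlignParams(**{**vars(params), "min_score": 0.5 * period})
    alignments = align_fragment(target, chain_id, query, params, allow_gaps=True)
    accepted: list[StructuralAlignment] = []
    covered: set = set()
    for aln in alignments:  # already sorted by score desc, start asc
        tset = aln.target_indices()
        if len(tset & covered) > 0.1 * period:
            continue
        accepted.append(aln)
        covered |= tset
    if not accepted:
        log.warning("no placement of the query reached score %.1f on %s",
                    0.5 * period, target.source_id)
        return RepeatArray(target.source_id, chain_id, [], str(query.parent.source_id),
                           period)
    accepted.sort(key=lambda a: a.target_start)
    units = []
    for aln in accepted:
        cmap = {t: q + 1 for q, t in aln.pairs}
        units.append(
            RepeatUnit(
                start=aln.target_start,
                end=aln.target_end,
                canonical_map=cmap,
                alignment=aln,
            )
        )
    # unaligned residues between consecutive units attach to the preceding
    # unit as a trailing insertion
    for k in range(len(units) - 1):
        gap = units[k + 1].start - units[k].end
        units[k].trailing_insertion = max(gap, 0)
    array = RepeatArray(target.source_id, chain_id, units,
                        str(query.parent.source_id), period)
    return classify_repeats(array)


def classify_repeats(array: RepeatArray) -> RepeatArray:
    """First unit N-terminal, last C-terminal, the rest internal."""
    if not array.units:
        raise ValueError("cannot classify an empty repeat array")
    n = len(array.units)
    if n == 1:
        log.warning(
            "single-unit array in %s: classified N_TERMINAL by convention",
            array.target_id,
        )
        array.units[0].klass = N_TERMINAL
        return array
    for k, u in enumerate(array.units):
        u.klass = N_TERMINAL if k == 0 else C_TERMINAL if k == n - 1 else INTERNAL
    return array


@dataclass
class MSARow:
    label: str
    text: str
    is_query: bool
    target_id: str = ""
    unit_index: int = -1


@dataclass
class StructMSA:
    rows: list  # of MSARow; query row(s) first
    column_canonical: list  # per column: canonical position 1..p, or None
    period: int

    @property
    def width(self) -> int:
        return len(self.column_canonical)

    def query_rows(self) -> list:
        return [r for r in self.rows if r.is_query]

    def target_rows(self) -> list:
        return [r for r in self.rows if not r.is_query]


def _unit_row_parts(unit: RepeatUnit, target_seq: str, period: int,
                    include_trailing: bool = True):
    """Per canonical position: the aligned residue (or None) and the list of
    insertion residues that follow it before the next aligned position."""
    aligned: dict[int, str] = {}
    insertions: dict[int, list] = {c: [] for c in range(period + 1)}
    inv = sorted(unit.canonical_map.items())  # (target idx, canonical)
    pos_of = dict(inv)
    last_canon = 0
    for t in range(unit.start, unit.end):
        c = pos_of.get(t)
        if c is None:
            insertions[last_canon].append(target_seq[t])
        else:
            aligned[c] = target_seq[t]
            last_canon = c
    if include_trailing and unit.trailing_insertion:
        for t in range(unit.end, unit.end + unit.trailing_insertion):
            insertions[period].append(target_seq[t])
    return aligned, insertions


def build_struct_msa(
    query: Fragment,
    targets: Sequence[tuple[StructureModel, str]],
    period: int,
    params: Optional[AlignParams] = None,
    arrays: Optional[Sequence[RepeatArray]] = None,
) -> tuple[StructMSA, list]:
    """Transitive structure-based MSA over all detected repeats.

    Returns the MSA together with the repeat arrays used (detected here
    unless supplied). The query sequence appears as a single leading row;
    with per-alignment query rows they would all be byte-identical, which is
    exactly the gap-redistribution guarantee.
    """
    if arrays is None:
        arrays = [
            detect_repeats(t, cid, query, period, params) for t, cid in targets
        ]
    pairs = []  # (array, target_seq)
    for (t, cid), arr in zip(targets, arrays):
        if arr.units:
            pairs.append((arr, t.sequence(cid)))
    if not pairs:
        raise ValueError("no repeats detected in any target")
    # widest insertion block after each canonical position (0 = before pos 1)
    ins_width = {c: 0 for c in range(period + 1)}
    per_unit = []
    for arr, seq in pairs:
        for k, unit in enumerate(arr.units):
            aligned, insertions = _unit_row_parts(unit, seq, period)
            per_unit.append((arr, k, aligned, insertions))
            for c, chars in insertions.items():
                ins_width[c] = max(ins_width[c], len(chars))
    column_canonical: list = [None] * ins_width[0]
    for c in range(1, period + 1):
        column_canonical.append(c)
        column_canonical.extend([None] * ins_width[c])
    qseq = query.sequence()
    qrow = []
    qrow.extend("-" * ins_width[0])
    for c in range(1, period + 1):
        qrow.append(qseq[c - 1])
        qrow.extend("-" * ins_width[c])
    rows = [MSARow(label="query", text="".join(qrow), is_query=True,
                   target_id=str(query.parent.source_id))]
    for arr, k, aligned, insertions in per_unit:
        parts = []
        block = insertions.get(0, [])
        parts.append("".join(block).ljust(ins_width[0], "-"))
        for c in range(1, period + 1):
            parts.append(aligned.get(c, "-"))
            block = insertions.get(c, [])
            parts.append("".join(block).ljust(ins_width[c], "-"))
        rows.append(
            MSARow(
                label=f"{arr.target_id}/{arr.chain_id}:{k}",
                text="".join(parts),
                is_query=False,
                target_id=arr.target_id,
                unit_index=k,
            )
        )
    msa = StructMSA(rows=rows, column_canonical=column_canonical, period=period)
    return msa, list(arrays)


def annotate_indels(msa: StructMSA, arrays: Sequence[RepeatArray]) -> list:
    """Maximal gap runs in the canonical frame.

    Insertions: residues of a target row in insertion columns (gap columns
    of the query rows); deletions: gap runs of a target row across canonical
    columns.
    """
    out = []
    canon = msa.column_canonical
    for row in msa.target_rows():
        # insertions: runs of residues in non-canonical columns
        j = 0
        while j < msa.width:
            if canon[j] is None and row.text[j] != "-":
                j0 = j
                while j < msa.width and canon[j] is None and row.text[j] != "-":
                    j += 1
                prev = [c for c in canon[:j0] if c is not None]
                pos = prev[-1] if prev else 1
                out.append(
                    IndelAnnotation(INSERTION, pos, j - j0, row.unit_index,
                                    row.target_id)
                )
            else:
                j += 1
        # deletions: gap runs over canonical columns
        gap_run = []
        for j in range(msa.width):
            if canon[j] is None:
                continue
            if row.text[j] == "-":
                gap_run.append(canon[j])
            else:
                if gap_run:
                    out.append(
                        IndelAnnotation(DELETION, gap_run[0], len(gap_run),
                                        row.unit_index, row.target_id)
                    )
                    gap_run = []
        if gap_run:
            out.append(
                IndelAnnotation(DELETION, gap_run[0], len(gap_run),
                                row.unit_index, row.target_id)
            )
    return out


def export_msa(msa: StructMSA, path, fmt: str = "FASTA") -> None:
    """Write the alignment as FASTA or Stockholm (gap character '-')."""
    if not msa.rows:
        raise ValueError("empty MSA")
    records = [
        SeqRecord(Seq(r.text), id=r.label.replace(" ", "_"), description="")
        for r in msa.rows
    ]
    aln = MultipleSeqAlignment(records)
    fmt_map = {"FASTA": "fasta", "STOCKHOLM": "stockholm"}
    try:
        bio_fmt = fmt_map[fmt.upper()]
    except KeyError:
        raise ValueError(f"unknown MSA format {fmt!r}")
    AlignIO.write(aln, str(path), bio_fmt)


def read_msa_rows(path, fmt: str = "FASTA") -> list:
    """Round-trip helper: (label, text) per row."""
    fmt_map = {"FASTA": "fasta", "STOCKHOLM": "stockholm"}
    aln = AlignIO.read(str(path), fmt_map[fmt.upper()])
    return [(rec.id, str(rec.seq)) for rec in aln]
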