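"""Cysteine census over transmembrane spans of a homolog alignment.

Disulfide substrates such as oxidized glutathione can form inhibitory mixed
disulfides with cysteine thiols they meet inside the translocation pathway,
so the distribution of cysteines across the transmembrane helices of a
transporter family is mechanistically informative.  This module maps the
columns of a multiple sequence alignment onto the reference (AtAtm3)
numbering, counts cysteines per reference position within declared TM spans,
and reports the overall TM cysteine frequency.

A simple conservation profile (normalized Shannon entropy over the 20 amino
acids, gaps excluded) is included as a monotone stand-in for phylogenetically
weighted conservation scores; it is qualitative by design.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from .errors import MappingError, SpanError
from .structure_io import write_table

#: Default AtAtm3 transmembrane spans (author numbering, inclusive).  TM6 is
#: the published 416-460; TM1-TM5 are approximations bracketing the helices,
#: placed so the TM cysteine positions reported for the family (149 in TM1,
#: 215 in TM2, 290 in TM3, 307 in TM4, 405 in TM5) fall within their helix.
DEFAULT_TM_SPANS: tuple[tuple[int, int, int], ...] = (
    (1, 135, 165),
    (2, 200, 230),
    (3, 255, 290),
    (4, 300, 330),
    (5, 380, 410),
    (6, 416, 460),
)

#: Conserved glutathione binding-pocket positions (AtAtm3 numbering).
BINDING_SITE_POSITIONS: tuple[int, ...] = (317, 324, 328, 387, 390, 433, 437, 441)


@dataclass
class Alignment:
    """A multiple sequence alignment with a designated reference row."""

    sequences: dict[str, str]
    reference_id: str

    def __post_init__(self):
        if self.reference_id not in self.sequences:
            raise MappingError(f"reference {self.reference_id!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise MappingError(f"aligned sequences differ in length: {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[self.reference_id])

    @property
    def reference(self) -> str:
        return self.sequences[self.reference_id]


def read_alignment(path: str | Path, reference_id: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    aln = AlignIO.read(str(path), "fasta")
    return Alignment({rec.id: str(rec.seq).upper() for rec in aln}, reference_id)


def write_alignment(aln: Alignment, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in aln.sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return path


@dataclass
class TMSpans:
    """Transmembrane helix intervals in reference numbering (inclusive)."""

    spans: tuple[tuple[int, int, int], ...] = DEFAULT_TM_SPANS  # (tm_index, start, end)

    def __post_init__(self):
        prev_end = None
        for _, start, end in self.spans:
            if start > end:
                raise ValueError(f"span {start}-{end} has start > end")
            if prev_end is not None and start <= prev_end:
                raise ValueError("TM spans must be non-overlapping and ascending")
            prev_end = end

    def tm_of(self, residue: int) -> int | None:
        for tm, start, end in self.spans:
            if start <= residue <= end:
                return tm
        return None

    def residues(self) -> list[int]:
        out = []
        for _, start, end in self.spans:
            out.extend(range(start, end + 1))
        return out


def map_columns_to_reference(aln: Alignment, offset: int | None = None
                             ) -> dict[int, int]:
    """Map alignment columns (0-based) to reference residue numbers.

    Columns where the reference is gapped are omitted.  Numbering starts at
    ``offset`` (default 1, i.e. the first residue of the supplied reference
    construct) and increases by one per non-gap reference column.
    """
    ref = aln.reference
    if all(c == "-" for c in ref):
        raise MappingError("reference sequence is all gaps")
    start = 1 if offset is None else int(offset)
    mapping: dict[int, int] = {}
    num = start
    for col, c in enumerate(ref):
        if c != "-":
            mapping[col] = num
            num += 1
    return mapping


@dataclass
class CensusResult:
    """Cysteine counts per TM reference position plus the overall frequency."""

    per_position: dict[int, int]
    overall_frequency: float        # percent of non-gap TM cells that are Cys
    n_sequences: int                # sequences counted (homologs by default)
    per_tm: dict[int, int] = field(default_factory=dict)
    binding_site_positions: tuple[int, ...] = BINDING_SITE_POSITIONS

    def to_table(self, spans: TMSpans, path: str | Path | None = None):
        rows = [{
            "position": pos,
            "tm_index": spans.tm_of(pos),
            "count": count,
            "is_binding_site": pos in self.binding_site_positions,
        } for pos, count in sorted(self.per_position.items())]
        if path is not None:
            return write_table(rows, path, format="tsv")
        return rows


def cysteine_census(aln: Alignment, spans: TMSpans | None = None,
                    offset: int | None = None,
                    include_reference: bool = False) -> CensusResult:
    """Count cysteines at each TM reference position across the alignment.

    The reference row is excluded by default (the census describes the
    homologs).  The overall frequency is 100 x (Cys cells) / (non-gap cells)
    over all TM columns of the counted sequences.
    """
    spans = spans if spans is not None else TMSpans()
    col_to_res = map_columns_to_reference(aln, offset=offset)
    res_to_col = {r: c for c, r in col_to_res.items()}
    mapped = set(res_to_col)
    out_of_range = [r for r in spans.residues() if r not in mapped]
    if out_of_range:
        raise SpanError(
            f"TM residues not covered by the reference mapping: "
            f"{out_of_range[:10]}{'...' if len(out_of_range) > 10 else ''}")

    names = [n for n in aln.sequences
             if include_reference or n != aln.reference_id]
    per_position: dict[int, int] = {}
    per_tm: dict[int, int] = {tm: 0 for tm, _, _ in spans.spans}
    cys_cells = 0
    nongap_cells = 0
    for tm, start, end in spans.spans:
        for res in range(start, end + 1):
            col = res_to_col[res]
            count = 0
            for name in names:
                c = aln.sequences[name][col]
                if c != "-":
                    nongap_cells += 1
                    if c == "C":
                        count += 1
            if count:
                per_position[res] = count
                per_tm[tm] += count
            cys_cells += count
    freq = 100.0 * cys_cells / nongap_cells if nongap_cells else 0.0
    return CensusResult(per_position=per_position, overall_frequency=freq,
                        n_sequences=len(names), per_tm=per_tm)


def conservation_profile(aln: Alignment, offset: int | None = None
                         ) -> dict[int, float]:
    """Normalized-entropy conservation score per reference position.

    Score 1 for invariant columns, 0 for a column uniform over the 20 amino
    acids: 1 - H/log(20), with H the Shannon entropy of the column's non-gap
    residue frequencies.  All-gap columns (outside the reference row) score 0.
    """
    if aln.n_sequences < 2:
        raise MappingError("conservation needs at least 2 sequences")
    col_to_res = map_columns_to_reference(aln, offset=offset)
    log20 = math.log(20.0)
    scores: dict[int, float] = {}
    for col, res in col_to_res.items():
        counts = Counter(seq[col] for seq in aln.sequences.values())
        counts.pop("-", None)
        total = sum(counts.values())
        if total == 0:
            scores[res] = 0.0
            continue
        h = -sum((n / total) * math.log(n / total) for n in counts.values())
        scores[res] = max(0.0, 1.0 - h / log20)
    return scores
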