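"""Ballesteros–Weinstein (BW) numbering from a class F alignment.

In the BW scheme the most conserved residue of transmembrane helix ``x``
is labelled ``x.50`` and its helix neighbours are offset by one per
residue (``x.49``, ``x.51``, ...). Given an alignment, per-helix anchor
columns (the x.50 reference positions) and helix column spans, this
module assigns a BW code to every residue of a chosen sequence and
scores per-column conservation.

Offsets are counted in ungapped sequence space of each sequence, not in
alignment-column space, so an insertion in one paralogue never shifts
another's numbering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AlignmentError",
    "BWScheme",
    "ResidueMap",
    "parse_alignment",
    "assign_bw",
    "conservation",
    "residue_at_bw",
]

GAP_CHARS = set("-.")


class AlignmentError(ValueError):
    """Malformed alignment or BW scheme input."""


def parse_alignment(path: str | Path, fmt: str | None = None) -> dict[str, str]:
    """Read a FASTA or Clustal alignment into ``{sequence id: aligned string}``.

    The format is sniffed from the first line unless ``fmt`` is given
    ("fasta" or "clustal"). Gap characters are preserved. Raises
    :class:`AlignmentError` if the aligned lengths are ragged.
    """
    from Bio import AlignIO

    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:  # Bio raises ValueError on ragged records
        raise AlignmentError(f"{path}: {exc}") from exc
    seqs = {rec.id: str(rec.seq) for rec in aln}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise AlignmentError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    if not seqs:
        raise AlignmentError(f"{path}: empty alignment")
    return seqs


@dataclass(frozen=True)
class BWScheme:
    """Anchor columns and helix spans defining a BW numbering.

    ``anchors`` maps helix number (1-7) to the 0-based alignment column
    holding that helix's x.50 reference residue; ``helix_ranges`` maps
    helix number to an inclusive 0-based column span. Every anchor must
    lie inside its span and spans must not overlap.
    """

    anchors: dict[int, int]
    helix_ranges: dict[int, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = []
        for helix, col in self.anchors.items():
            if helix not in self.helix_ranges:
                raise AlignmentError(f"helix {helix}: anchor given without a span")
            lo, hi = self.helix_ranges[helix]
            if not (lo <= col <= hi):
                raise AlignmentError(
                    f"helix {helix}: anchor column {col} outside span [{lo}, {hi}]"
                )
            spans.append((lo, hi, helix))
        spans.sort()
        for (lo1, hi1, h1), (lo2, hi2, h2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise AlignmentError(f"helix spans {h1} and {h2} overlap")

    @classmethod
    def from_file(cls, path: str | Path) -> "BWScheme":
        """Load a scheme from a small JSON config:
        ``{"helices": {"6": {"anchor_col": 12, "span": [0, 25]}, ...}}``."""
        with open(path) as fh:
            cfg = json.load(fh)
        anchors = {}
        ranges = {}
        for key, entry in cfg["helices"].items():
            helix = int(key)
            anchors[helix] = int(entry["anchor_col"])
            lo, hi = entry["span"]
            ranges[helix] = (int(lo), int(hi))
        return cls(anchors, ranges)


@dataclass
class ResidueMap:
    """Bidirectional residue-index ↔ BW-code map for one sequence.

    Residue indices are 1-based positions in the ungapped sequence.
    """

    sequence_id: str
    to_bw: dict[int, str] = field(default_factory=dict)
    to_residue: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.to_residue and self.to_bw:
            self.to_residue = {bw: idx for idx, bw in self.to_bw.items()}
        if len(self.to_bw) != len(self.to_residue):
            raise AlignmentError(f"{self.sequence_id}: residue↔BW map is not bijective")

    def bw(self, residue_index: int) -> str:
        return self.to_bw[residue_index]

    def residue(self, bw_code: str) -> int:
        if bw_code not in self.to_residue:
            raise KeyError(f"{self.sequence_id}: BW position {bw_code} not mapped")
        return self.to_residue[bw_code]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"sequence_id": self.sequence_id,
                 "to_bw": {str(k): v for k, v in self.to_bw.items()}},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "ResidueMap":
        with open(path) as fh:
            data = json.load(fh)
        return cls(data["sequence_id"],
                   to_bw={int(k): v for k, v in data["to_bw"].items()})


def _ungapped_positions(aligned: str) -> np.ndarray:
    """Per alignment column: 1-based ungapped residue index, 0 at gaps."""
    out = np.zeros(len(aligned), dtype=int)
    k = 0
    for i, ch in enumerate(aligned):
        if ch not in GAP_CHARS:
            k += 1
            out[i] = k
    return out


def assign_bw(sequence_id: str, scheme: BWScheme, alignment: dict[str, str]) -> ResidueMap:
    """Assign BW codes to every non-gap residue of ``sequence_id`` inside
    each helix span.

    The residue at a helix's anchor column is ``x.50``; other residues in
    the span get ``x.(50 + offset)`` where the offset counts only that
    sequence's own non-gap residues. Raises if the sequence is gapped at
    an anchor column.
    """
    if sequence_id not in alignment:
        raise AlignmentError(f"sequence {sequence_id!r} not in alignment")
    aligned = alignment[sequence_id]
    pos = _ungapped_positions(aligned)

    to_bw: dict[int, str] = {}
    for helix, anchor_col in scheme.anchors.items():
        if aligned[anchor_col] in GAP_CHARS:
            raise AlignmentError(
                f"{sequence_id}: gap at helix {helix} anchor column {anchor_col}"
            )
        anchor_res = pos[anchor_col]
        lo, hi = scheme.helix_ranges[helix]
        for col in range(lo, hi + 1):
            if aligned[col] in GAP_CHARS:
                continue
            number = 50 + (pos[col] - anchor_res)
            to_bw[int(pos[col])] = f"{helix}.{number}"
    return ResidueMap(sequence_id, to_bw=to_bw)


def conservation(alignment: dict[str, str]) -> np.ndarray:
    """Per-column conservation in [0, 1]: frequency of the modal non-gap
    residue among non-gap entries; all-gap columns score 0."""
    if len(alignment) < 2:
        raise AlignmentError("conservation requires at least 2 sequences")
    seqs = list(alignment.values())
    ncol = len(seqs[0])
    scores = np.zeros(ncol)
    for col in range(ncol):
        counts: dict[str, int] = {}
        total = 0
        for s in seqs:
            ch = s[col]
            if ch in GAP_CHARS:
                continue
            counts[ch.upper()] = counts.get(ch.upper(), 0) + 1
            total += 1
        scores[col] = max(counts.values()) / total if total else 0.0
    return scores


def residue_at_bw(
    alignment: dict[str, str], scheme: BWScheme, bw_code: str, gap_marker: str = "-"
) -> dict[str, str]:
    """The residue letter each sequence carries at a BW position.

    Returns ``{sequence id: letter}`` with ``gap_marker`` where a sequence
    has no residue at that position. Raises if the code falls outside the
    helix span for every sequence.
    """
    helix_str, num_str = bw_code.split(".")
    helix = int(helix_str)
    if helix not in scheme.anchors:
        raise AlignmentError(f"BW code {bw_code}: helix {helix} not in scheme")
    offset = int(num_str) - 50
    anchor_col = scheme.anchors[helix]
    lo, hi = scheme.helix_ranges[helix]

    out: dict[str, str] = {}
    any_inside = False
    for sid, aligned in alignment.items():
        if aligned[anchor_col] in GAP_CHARS:
            out[sid] = gap_marker
            continue
        pos = _ungapped_positions(aligned)
        target = pos[anchor_col] + offset
        letter = gap_marker
        for col in range(lo, hi + 1):
            if aligned[col] not in GAP_CHARS and pos[col] == target:
                letter = aligned[col]
                any_inside = True
                break
        out[sid] = letter
    if not any_inside:
        raise AlignmentError(f"BW code {bw_code} outside helix {helix} span for all sequences")
    return out
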