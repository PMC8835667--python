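"""Sequence-logo matrices and positional frequency tables.

Column conservation is expressed as information content above the
background: the relative entropy (in bits) of the observed residue
frequencies against the null composition,

    IC = sum_a p_a * log2(p_a / q_a),

with letter heights IC * p_a, so the stacked letters of a column sum to
its information content.  The companion frequency tables count specific
(position, residue) queries per subgroup -- the "interaction code"
readout of which side-chain occupies a frame position how often in each
KRAB family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import (
    AA_INDEX,
    AMINO_ACIDS,
    KrabCoordinate,
    is_gap,
    normalize_residue,
)
from .errors import DataError, ValidationError


@dataclass
class ColumnFrequencies:
    """Per-column residue counts of one alignment.

    ``counts`` is (n_columns, 20); X-class residues are excluded from the
    counts but still occupy their column, so they appear in ``x_counts``
    and contribute to occupancy.
    """

    counts: np.ndarray
    gap_counts: np.ndarray
    x_counts: np.ndarray
    n_rows: int

    @property
    def n_columns(self) -> int:
        return self.counts.shape[0]

    def occupancy(self) -> np.ndarray:
        """Fraction of rows with any residue (including X) per column."""
        return 1.0 - self.gap_counts / self.n_rows

    def column(self, j: int) -> Dict[str, int]:
        return {
            AMINO_ACIDS[i]: int(self.counts[j, i])
            for i in range(20)
            if self.counts[j, i] > 0
        }


def column_frequencies(alignment: Sequence[str]) -> ColumnFrequencies:
    """Count residues, gaps and X-class characters per alignment column."""
    rows = list(alignment)
    if not rows:
        raise DataError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise DataError("alignment rows must have uniform length")
    counts = np.zeros((width, 20), dtype=int)
    gaps = np.zeros(width, dtype=int)
    xs = np.zeros(width, dtype=int)
    for r in rows:
        for j, ch in enumerate(r):
            if is_gap(ch):
                gaps[j] += 1
                continue
            c = normalize_residue(ch)
            if c == "X":
                xs[j] += 1
            else:
                counts[j, AA_INDEX[c]] += 1
    return ColumnFrequencies(counts=counts, gap_counts=gaps, x_counts=xs, n_rows=len(rows))


def information_content(
    column_counts: Union[np.ndarray, Mapping[str, int]],
    background: Optional[np.ndarray] = None,
) -> Tuple[float, Dict[str, float]]:
    """Information content (bits) of one column plus letter heights.

    Frequencies come straight from the counts, without pseudocounts;
    residues never observed contribute nothing.  With a uniform
    background a single-residue column reaches log2(20) bits.
    """
    if isinstance(column_counts, Mapping):
        vec = np.zeros(20)
        for res, cnt in column_counts.items():
            vec[AA_INDEX[normalize_residue(res)]] = cnt
    else:
        vec = np.asarray(column_counts, float)
    total = vec.sum()
    if total <= 0:
        raise ValidationError("column has no observed residues")
    q = np.full(20, 1.0 / 20.0) if background is None else np.asarray(background, float)
    p = vec / total
    observed = p > 0
    ic = float(np.sum(p[observed] * np.log2(p[observed] / q[observed])))
    heights = {AMINO_ACIDS[i]: float(ic * p[i]) for i in range(20) if p[i] > 0}
    return ic, heights


@dataclass
class LogoMatrix:
    """Logo data: per-column letter heights and information content."""

    columns: List[Union[KrabCoordinate, int]]
    heights: List[Dict[str, float]]
    ic: List[float]
    occupancy: List[float]

    def __post_init__(self) -> None:
        n = len(self.columns)
        if not (len(self.heights) == len(self.ic) == len(self.occupancy) == n):
            raise ValidationError("logo matrix fields must have equal length")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col, h, ic, occ in zip(self.columns, self.heights, self.ic, self.occupancy):
            row = {"column": str(col), "ic": ic, "occupancy": occ}
            row.update({a: h.get(a, 0.0) for a in AMINO_ACIDS})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def logo_matrix(
    alignment: Sequence[str],
    columns: Optional[Sequence[Union[KrabCoordinate, int]]] = None,
    background: Optional[np.ndarray] = None,
) -> LogoMatrix:
    """Build the logo matrix of an alignment.

    Columns with no observed residues get zero information content
    rather than an error, so fully-gapped columns survive bookkeeping.
    """
    freqs = column_frequencies(alignment)
    cols = list(columns) if columns is not None else list(range(freqs.n_columns))
    if len(cols) != freqs.n_columns:
        raise ValidationError("columns must match alignment width")
    occ = freqs.occupancy()
    heights: List[Dict[str, float]] = []
    ics: List[float] = []
    for j in range(freqs.n_columns):
        if freqs.counts[j].sum() == 0:
            heights.append({})
            ics.append(0.0)
        else:
            ic, h = information_content(freqs.counts[j], background)
            heights.append(h)
            ics.append(ic)
    return LogoMatrix(columns=cols, heights=heights, ic=ics, occupancy=list(occ))


def plot_logo(matrix: LogoMatrix, path) -> None:
    """Render the logo matrix as a stacked-letter bar chart (optional layer)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(matrix.columns) * 0.3), 3))
    for j, h in enumerate(matrix.heights):
        bottom = 0.0
        for res, height in sorted(h.items(), key=lambda kv: kv[1]):
            ax.bar(j, height, bottom=bottom, width=0.9)
            if height > 0.25:
                ax.text(j, bottom + height / 2, res, ha="center", va="center", fontsize=6)
            bottom += height
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels([str(c) for c in matrix.columns], rotation=90, fontsize=5)
    ax.set_ylabel("information content (bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def drop_sparse_columns(
    alignment: Sequence[str], max_gap_fraction: float = 0.5
) -> Tuple[List[str], List[int]]:
    """Remove mostly-empty columns.

    Returns the reduced alignment and the original indices of the kept
    columns, so frame coordinates can be carried along.
    """
    freqs = column_frequencies(alignment)
    gap_frac = freqs.gap_counts / freqs.n_rows
    kept = [j for j in range(freqs.n_columns) if gap_frac[j] <= max_gap_fraction]
    if not kept:
        raise DataError("all columns exceed the gap-fraction limit")
    reduced = ["".join(row[j] for j in kept) for row in alignment]
    return reduced, kept


@dataclass
class FrequencyTable:
    """(position, residue) counts per subgroup with their denominators."""

    rows: List[Tuple[KrabCoordinate, str]]
    per_subgroup: Dict[str, List[Tuple[int, int]]]  # subgroup -> [(count, denom)]

    def __post_init__(self) -> None:
        for sub, cells in self.per_subgroup.items():
            if len(cells) != len(self.rows):
                raise ValidationError(f"subgroup {sub} has wrong row count")
            for count, denom in cells:
                if not 0 <= count <= denom:
                    raise ValidationError(f"count {count} outside 0..{denom}")

    def to_frame(self) -> pd.DataFrame:
        data = []
        for i, (coord, res) in enumerate(self.rows):
            row: Dict[str, object] = {"position": str(coord), "residue": res}
            for sub, cells in self.per_subgroup.items():
                count, denom = cells[i]
                row[sub] = f"{count}/{denom}"
            data.append(row)
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def position_counts(
    subgroup_alignments: Mapping[str, Sequence[str]],
    queries: Sequence[Tuple[KrabCoordinate, str]],
    frame: Sequence[KrabCoordinate],
) -> FrequencyTable:
    """Count how often each queried residue occupies its frame position.

    Every subgroup alignment must be laid out over the shared KRAB
    ``frame``.  The denominator of a cell is the number of sequences
    with any residue at that column (B positions are counted in all
    sequences, whether or not a conserved KRAB-B exists).  A query
    coordinate outside the frame is an error; an empty subgroup yields
    (0, 0) cells.
    """
    col_of = {coord: j for j, coord in enumerate(frame)}
    for coord, _ in queries:
        if coord not in col_of:
            raise ValidationError(f"query coordinate {coord} outside the frame")
    per_subgroup: Dict[str, List[Tuple[int, int]]] = {}
    for sub, alignment in subgroup_alignments.items():
        rows = list(alignment)
        if rows:
            freqs = column_frequencies(rows)
            if freqs.n_columns != len(frame):
                raise ValidationError(
                    f"subgroup {sub}: alignment width {freqs.n_columns} != frame {len(frame)}"
                )
        cells: List[Tuple[int, int]] = []
        for coord, res in queries:
            if not rows:
                cells.append((0, 0))
                continue
            j = col_of[coord]
            denom = freqs.n_rows - int(freqs.gap_counts[j])
            count = int(freqs.counts[j, AA_INDEX[normalize_residue(res)]])
            cells.append((count, denom))
        per_subgroup[sub] = cells
    return FrequencyTable(rows=[(c, normalize_residue(r)) for c, r in queries],
                          per_subgroup=per_subgroup)
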