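"""Core data model: the KRAB coordinate system, sequences and the catalog.

A KRAB domain is addressed with per-subdomain 1-based coordinates
(A1..A42 for KRAB-A, B1..B35 for KRAB-B).  Ancestral-type (aKRAB)
domains leave position A32 unoccupied -- the hallmark alignment gap
opposite the modern MLE motif -- which is represented here as an
*unmapped coordinate*, never as a gap character inside the stored
residue string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import AlphabetError, DataError, ValidationError

#: Canonical 20-letter amino-acid alphabet, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Ambiguity / rare codes accepted on input and treated as X for scoring.
X_CLASS = frozenset("BZXU")

GAP_CHARS = frozenset("-.")

#: Subdomain spans of the KRAB blueprint.
SUBDOMAIN_SPAN = {"A": 42, "B": 35}
_SUBDOMAIN_ORDER = {"A": 0, "B": 1}

_COORD_RE = re.compile(r"^([AB])(\d+)$")

#: Canonical subgroup labels.
SUBGROUPS = ("PRDM9_ortho", "SSX_ortho", "lcha_ZNF", "hs_mKRAB", "unknown")


def is_gap(ch: str) -> bool:
    return ch in GAP_CHARS


def normalize_residue(ch: str) -> str:
    """Uppercase a residue character, mapping ambiguity codes to X.

    Raises AlphabetError for anything that is neither a standard amino
    acid nor an accepted ambiguity code.
    """
    c = ch.upper()
    if c in AA_INDEX:
        return c
    if c in X_CLASS:
        return "X"
    raise AlphabetError(f"not an amino-acid character: {ch!r}")


@total_ordering
@dataclass(frozen=True)
class KrabCoordinate:
    """A position in the KRAB frame, e.g. A32 or B14.

    All A positions precede all B positions; comparison is total.
    """

    subdomain: str
    position: int

    def __post_init__(self) -> None:
        if self.subdomain not in SUBDOMAIN_SPAN:
            raise ValidationError(f"unknown subdomain {self.subdomain!r}")
        span = SUBDOMAIN_SPAN[self.subdomain]
        if not 1 <= self.position <= span:
            raise ValidationError(
                f"{self.subdomain} position must be in 1..{span}, got {self.position}"
            )

    @classmethod
    def from_string(cls, text: str) -> "KrabCoordinate":
        m = _COORD_RE.match(text.strip())
        if not m:
            raise ValidationError(f"cannot parse KRAB coordinate {text!r}")
        return cls(m.group(1), int(m.group(2)))

    def _key(self) -> Tuple[int, int]:
        return (_SUBDOMAIN_ORDER[self.subdomain], self.position)

    def __lt__(self, other: "KrabCoordinate") -> bool:
        return self._key() < other._key()

    def __str__(self) -> str:
        return f"{self.subdomain}{self.position}"


def full_frame(subdomains: Sequence[str] = ("A", "B")) -> List[KrabCoordinate]:
    """The ordered list of all coordinates of the requested subdomains."""
    cols: List[KrabCoordinate] = []
    for sub in subdomains:
        cols.extend(KrabCoordinate(sub, p) for p in range(1, SUBDOMAIN_SPAN[sub] + 1))
    return cols


#: Module-level frames, computed once.
FRAME_AB = full_frame(("A", "B"))
FRAME_A = full_frame(("A",))
FRAME_B = full_frame(("B",))

A32 = KrabCoordinate("A", 32)


@dataclass
class KrabSequence:
    """An ungapped protein segment with KRAB-frame annotations.

    ``coord_map`` maps KrabCoordinate -> 0-based index into ``residues``.
    The map is injective and strictly increasing with coordinate order;
    residues without a coordinate (e.g. engineered insertions) are legal.
    """

    residues: str
    coord_map: Dict[KrabCoordinate, int] = field(default_factory=dict)
    source_id: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.residues = "".join(normalize_residue(c) for c in self.residues)
        n = len(self.residues)
        seen_idx = set()
        prev: Optional[Tuple[KrabCoordinate, int]] = None
        for coord in sorted(self.coord_map):
            idx = self.coord_map[coord]
            if not 0 <= idx < n:
                raise ValidationError(f"coord {coord} maps outside sequence (index {idx})")
            if idx in seen_idx:
                raise ValidationError(f"coord_map is not injective at index {idx}")
            seen_idx.add(idx)
            if prev is not None and idx <= prev[1]:
                raise ValidationError(
                    f"coordinate order violated: {prev[0]}->{prev[1]} then {coord}->{idx}"
                )
            prev = (coord, idx)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, coord: KrabCoordinate) -> Optional[str]:
        """Residue mapped at ``coord``, or None when the coordinate is unmapped."""
        idx = self.coord_map.get(coord)
        return None if idx is None else self.residues[idx]

    def mapped_coordinates(self) -> List[KrabCoordinate]:
        return sorted(self.coord_map)

    def to_aligned(self, columns: Sequence[KrabCoordinate]) -> str:
        """Re-emit the sequence as a gapped row over the given columns.

        Residues whose coordinate is not among ``columns`` (or that carry
        no coordinate at all) are not representable in a fixed frame and
        are omitted.
        """
        return "".join(
            self.residues[self.coord_map[c]] if c in self.coord_map else "-"
            for c in columns
        )


def map_alignment_to_coordinates(
    aligned_seq: str,
    reference_columns: Sequence[KrabCoordinate],
    source_id: str = "",
    species: str = "",
) -> KrabSequence:
    """Project one gapped alignment row onto KRAB coordinates.

    Each non-gap character receives the coordinate of its column; gap
    columns stay unmapped.  The row and the column list must have equal
    length.
    """
    if len(aligned_seq) != len(reference_columns):
        raise ValidationError(
            f"aligned row length {len(aligned_seq)} != {len(reference_columns)} columns"
        )
    residues: List[str] = []
    coord_map: Dict[KrabCoordinate, int] = {}
    for ch, coord in zip(aligned_seq, reference_columns):
        if is_gap(ch):
            continue
        residues.append(normalize_residue(ch))
        coord_map[coord] = len(residues) - 1
    return KrabSequence("".join(residues), coord_map, source_id=source_id, species=species)


def length_delta(a: KrabSequence, b: KrabSequence) -> int:
    """Signed length difference len(b) - len(a).

    The one-residue surplus of an mKRAB-style domain over its aKRAB
    counterpart (the filled A32) shows up here as +1.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("length_delta requires non-empty sequences")
    return len(b) - len(a)


@dataclass
class CatalogEntry:
    """One domain occurrence: sequence, species, subgroup and raw E-values.

    ``scores`` holds raw model E-values (> 0); a missing key means the
    model was never scored, which is distinct from a clamped score (the
    clamping transform lives in :mod:`krabstrat.stratify`).
    """

    id: str
    species: str
    domain_seq: KrabSequence
    subgroup: str = "unknown"
    scores: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entry id must be non-empty")
        if not self.species:
            raise ValidationError(f"entry {self.id}: species must be non-empty")
        if self.subgroup not in SUBGROUPS:
            raise ValidationError(f"entry {self.id}: unknown subgroup {self.subgroup!r}")
        for model, ev in self.scores.items():
            if not ev > 0:
                raise ValidationError(
                    f"entry {self.id}: E-value for {model} must be > 0, got {ev}"
                )


class Catalog:
    """An ordered collection of catalog entries with unique ids."""

    def __init__(self, entries: Iterable[CatalogEntry] = ()) -> None:
        self.entries: List[CatalogEntry] = list(entries)
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate catalog ids: {dupes}")
        self._by_id = {e.id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def __getitem__(self, entry_id: str) -> CatalogEntry:
        return self._by_id[entry_id]

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._by_id

    def ids(self) -> List[str]:
        return [e.id for e in self.entries]

    # ------------------------------------------------------------------
    # TSV round trip.  Layout: id, species, subgroup, sequence (gapped row
    # over the frame, '-' written, '.' accepted), then optional per-model
    # E-value columns named "E:<model>".
    # ------------------------------------------------------------------

    def to_tsv(self, path: str | Path, columns: Sequence[KrabCoordinate] = FRAME_AB) -> None:
        models = sorted({m for e in self.entries for m in e.scores})
        rows = []
        for e in self.entries:
            row = {
                "id": e.id,
                "species": e.species,
                "subgroup": e.subgroup,
                "sequence": e.domain_seq.to_aligned(columns),
            }
            for m in models:
                row[f"E:{m}"] = e.scores.get(m, "")
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, columns: Sequence[KrabCoordinate] = FRAME_AB) -> "Catalog":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise DataError(f"cannot read catalog TSV {path}: {exc}") from exc
        required = {"id", "species", "sequence"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"catalog TSV {path} lacks columns: {sorted(missing)}")
        model_cols = [c for c in df.columns if c.startswith("E:")]
        entries = []
        for _, row in df.iterrows():
            seq = map_alignment_to_coordinates(
                row["sequence"], columns, source_id=row["id"], species=row["species"]
            )
            scores = {}
            for c in model_cols:
                if row[c] != "":
                    scores[c[2:]] = float(row[c])
            entries.append(
                CatalogEntry(
                    id=row["id"],
                    species=row["species"],
                    subgroup=row.get("subgroup", "unknown") or "unknown",
                    domain_seq=seq,
                    scores=scores,
                )
            )
        return cls(entries)


# ----------------------------------------------------------------------
# Alignment file helpers (FASTA / ClustalW .aln / Stockholm via Biopython)
# ----------------------------------------------------------------------

def read_alignment(path: str | Path, fmt: Optional[str] = None) -> List[Tuple[str, str]]:
    """Read a multiple alignment as (name, gapped row) pairs.

    The format is inferred from the file suffix when not given:
    ``.aln`` -> clustal, ``.sto``/``.stk`` -> stockholm, else fasta.
    """
    from Bio import AlignIO

    p = Path(path)
    if fmt is None:
        fmt = {
            ".aln": "clustal",
            ".sto": "stockholm",
            ".stk": "stockholm",
        }.get(p.suffix.lower(), "fasta")
    try:
        aln = AlignIO.read(str(p), fmt)
    except Exception as exc:
        raise DataError(f"cannot read alignment {path} as {fmt}: {exc}") from exc
    return [(rec.id, str(rec.seq)) for rec in aln]


def write_fasta(path: str | Path, records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
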