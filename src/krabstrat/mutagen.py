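"""Edit scripts in KRAB coordinates: the ancestral-to-modern roadmap.

An edit addresses a coordinate span ("A27:R>V", "A32-A34:KR>MLE") and
replaces the residues *mapped* within that span.  The MLE insertion is
the canonical length-changing case: wild-type ancestral domains carry
K and R at A33-A34 with A32 unmapped (the alignment gap), and the
replacement puts M, L, E onto A32, A33, A34 -- one residue longer.

Coordinate conventions for replacements:

- fewer residues than span coordinates: residues occupy the *last*
  coordinates of the span (the gap leads, as in the ancestral
  alignment), so inverting the MLE insertion restores gap-KR exactly;
- more residues than span coordinates: the leading residues take the
  span coordinates and the surplus trails unmapped (an insertion after
  the span, e.g. the helix-breaking "A33:L>LPP" double proline).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .core import KrabCoordinate, KrabSequence, full_frame
from .errors import (
    DataError,
    UnderdeterminedConstructError,
    ValidationError,
)

_EDIT_RE = re.compile(
    r"^([AB]\d+)(?:-([AB]\d+))?:([A-Z]*)>([A-Z]*)$"
)


@dataclass(frozen=True)
class Edit:
    """One substitution or block replacement over a coordinate span."""

    kind: str  # "substitution" | "block_replacement"
    start: KrabCoordinate
    end: KrabCoordinate
    from_residues: str
    to_residues: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "block_replacement"):
            raise ValidationError(f"unknown edit kind {self.kind!r}")
        if self.end < self.start:
            raise ValidationError(f"edit span {self.start}-{self.end} is reversed")
        if self.kind == "substitution":
            if len(self.from_residues) != 1 or len(self.to_residues) != 1:
                raise ValidationError("substitution must replace exactly one residue")
            if self.start != self.end:
                raise ValidationError("substitution span must be a single coordinate")
        if not self.from_residues and not self.to_residues:
            raise ValidationError("edit replaces nothing with nothing")

    @property
    def length_delta(self) -> int:
        return len(self.to_residues) - len(self.from_residues)

    def span_coordinates(self) -> List[KrabCoordinate]:
        return [c for c in full_frame() if self.start <= c <= self.end]

    def inverse(self) -> "Edit":
        kind = (
            "substitution"
            if len(self.to_residues) == 1 and len(self.from_residues) == 1
            and self.start == self.end
            else "block_replacement"
        )
        return Edit(kind, self.start, self.end, self.to_residues, self.from_residues)

    def __str__(self) -> str:
        span = str(self.start) if self.start == self.end else f"{self.start}-{self.end}"
        return f"{span}:{self.from_residues}>{self.to_residues}"


def parse_edit(spec: str) -> Edit:
    """Parse the edit grammar, e.g. "A27:R>V" or "A32-A34:KR>MLE"."""
    m = _EDIT_RE.match(spec.strip())
    if not m:
        raise ValidationError(f"malformed edit spec {spec!r}")
    start = KrabCoordinate.from_string(m.group(1))
    end = KrabCoordinate.from_string(m.group(2)) if m.group(2) else start
    from_res, to_res = m.group(3), m.group(4)
    kind = (
        "substitution"
        if start == end and len(from_res) == 1 and len(to_res) == 1
        else "block_replacement"
    )
    return Edit(kind, start, end, from_res, to_res)


@dataclass
class EditScript:
    """An ordered, non-overlapping collection of edits."""

    name: str
    edits: List[Edit] = field(default_factory=list)
    provenance: str = "fully_specified"  # or "figure_dependent"
    wild_type: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in ("fully_specified", "figure_dependent"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        self.edits = sorted(self.edits, key=lambda e: e.start)
        for prev, nxt in zip(self.edits, self.edits[1:]):
            if not prev.end < nxt.start:
                raise ValidationError(
                    f"script {self.name}: edits {prev} and {nxt} overlap"
                )

    @property
    def length_delta(self) -> int:
        return sum(e.length_delta for e in self.edits)

    def inverse(self) -> "EditScript":
        return EditScript(
            name=f"{self.name}-inverse",
            edits=[e.inverse() for e in self.edits],
            provenance=self.provenance,
            wild_type=self.wild_type,
        )


@dataclass
class DiffInventory:
    """Edit tally of a wild-type/mutant pair."""

    n_substitutions: int
    n_block_replacements: int
    length_delta: int
    positions: List[str]


# ----------------------------------------------------------------------
# Script application
# ----------------------------------------------------------------------

def _to_items(seq: KrabSequence) -> List[Tuple[Optional[KrabCoordinate], str]]:
    """Sequence as ordered (coordinate-or-None, residue) items."""
    idx_to_coord = {i: c for c, i in seq.coord_map.items()}
    return [(idx_to_coord.get(i), seq.residues[i]) for i in range(len(seq.residues))]


def _from_items(
    items: Sequence[Tuple[Optional[KrabCoordinate], str]],
    source_id: str,
    species: str,
) -> KrabSequence:
    residues = "".join(res for _, res in items)
    coord_map = {c: i for i, (c, _) in enumerate(items) if c is not None}
    return KrabSequence(residues, coord_map, source_id=source_id, species=species)


def _anchor(items, i) -> Optional[KrabCoordinate]:
    """Coordinate governing item i: its own, else the previous mapped one."""
    for j in range(i, -1, -1):
        if items[j][0] is not None:
            return items[j][0]
    return None


def apply_script(seq: KrabSequence, script: EditScript) -> KrabSequence:
    """Apply an edit script; refuses on any residue mismatch.

    An edit's region is the run of items anchored within its span: a
    mapped residue belongs to its own coordinate, an unmapped residue to
    the nearest mapped coordinate before it.  The concatenated region
    residues must equal the edit's from_residues.
    """
    if script.provenance == "figure_dependent":
        raise UnderdeterminedConstructError(
            f"construct {script.name} is only defined graphically; "
            "its residue composition is not available for application"
        )
    items = _to_items(seq)
    for edit in script.edits:
        span = edit.span_coordinates()
        region = [
            i for i in range(len(items))
            if (a := _anchor(items, i)) is not None and edit.start <= a <= edit.end
        ]
        found = "".join(items[i][1] for i in region)
        if found != edit.from_residues:
            where = str(edit.start) if edit.start == edit.end else f"{edit.start}-{edit.end}"
            raise ValidationError(
                f"script {script.name}: edit {edit} does not match sequence "
                f"{seq.source_id or '<unnamed>'} at {where}: found {found!r}"
            )
        # Build replacement items with the span-alignment convention.
        n_coords = len(span)
        n_res = len(edit.to_residues)
        new_items: List[Tuple[Optional[KrabCoordinate], str]] = []
        if n_res <= n_coords:
            coords = span[n_coords - n_res:]  # right-aligned: the gap leads
            new_items = list(zip(coords, edit.to_residues))
        else:
            for i, res in enumerate(edit.to_residues):
                new_items.append((span[i] if i < n_coords else None, res))
        if region:
            lo, hi = region[0], region[-1] + 1
        else:
            # Pure insertion into an empty region: place after the last
            # item anchored before the span.
            lo = hi = next(
                (i for i in range(len(items))
                 if items[i][0] is not None and items[i][0] > edit.end),
                len(items),
            )
        items = items[:lo] + new_items + items[hi:]
    return _from_items(items, source_id=f"{seq.source_id}:{script.name}", species=seq.species)


def diff_inventory(
    wild_type: KrabSequence, mutant: KrabSequence, script: EditScript
) -> DiffInventory:
    """Tally a script after checking it really produces the mutant."""
    produced = apply_script(wild_type, script)
    if produced.residues != mutant.residues or produced.coord_map != mutant.coord_map:
        raise DataError(
            f"script {script.name} applied to {wild_type.source_id or '<wt>'} "
            "does not reproduce the given mutant"
        )
    subs = sum(1 for e in script.edits if e.kind == "substitution")
    blocks = sum(1 for e in script.edits if e.kind == "block_replacement")
    positions = [str(e) for e in script.edits]
    return DiffInventory(
        n_substitutions=subs,
        n_block_replacements=blocks,
        length_delta=script.length_delta,
        positions=positions,
    )


def assemble_hybrid(
    a_domain: KrabSequence, b_domain: Optional[KrabSequence]
) -> KrabSequence:
    """Concatenate an A-subdomain construct with a B subdomain.

    An empty/None B yields the A-only construct (the ablated-B control).
    The two coordinate frames must not overlap and A must precede B.
    """
    if b_domain is None or len(b_domain) == 0:
        return KrabSequence(
            a_domain.residues,
            dict(a_domain.coord_map),
            source_id=a_domain.source_id,
            species=a_domain.species,
        )
    a_coords = a_domain.mapped_coordinates()
    b_coords = b_domain.mapped_coordinates()
    if a_coords and b_coords and not a_coords[-1] < b_coords[0]:
        raise ValidationError(
            f"overlapping coordinate frames: A ends at {a_coords[-1]}, "
            f"B starts at {b_coords[0]}"
        )
    offset = len(a_domain.residues)
    coord_map = dict(a_domain.coord_map)
    coord_map.update({c: i + offset for c, i in b_domain.coord_map.items()})
    return KrabSequence(
        a_domain.residues + b_domain.residues,
        coord_map,
        source_id=f"{a_domain.source_id}-{b_domain.source_id}",
        species=a_domain.species,
    )


# ----------------------------------------------------------------------
# The packaged construct roster
# ----------------------------------------------------------------------

def mutant_library() -> Dict[str, EditScript]:
    """Named edit scripts of the PRDM9/ZNF10 construct roster.

    Scripts whose residue content is stated in running text are
    ``fully_specified``; constructs defined only graphically ship as
    ``figure_dependent`` stubs that refuse application.
    """
    text = resources.files("krabstrat").joinpath("data/mutants.yaml").read_text()
    raw = yaml.safe_load(text)
    if raw.get("version") != 1:
        raise DataError("unsupported mutants.yaml version")
    library: Dict[str, EditScript] = {}
    for name, entry in raw["scripts"].items():
        edits = [parse_edit(e) for e in entry.get("edits", [])]
        library[name] = EditScript(
            name=name,
            edits=edits,
            provenance=entry.get("provenance", "fully_specified"),
            wild_type=entry.get("wild_type", ""),
        )
    return library
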