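"""Synthetic inputs: subgroup-structured KRAB catalogs and helix fixtures.

The four built-in generators emulate the conservation structure of the
KRAB families without any download: a shared scaffold consensus over
the A1-A42 / B1-B35 frame, group-specific redraws at a fraction of
positions, and the hallmark motifs planted on top --

- modern KRAB (hs_mKRAB): DV at A7-8, VMLE at A31-34, LE at B13-14,
  PW at B19-20;
- ancestral groups (PRDM9_ortho, SSX_ortho, lcha_ZNF): DI at A7-8,
  gap-KR over A32-A34 (nothing is ever emitted at A32), and the
  shared P..FM pattern around B7-B10;
- PRDM9 orthologs additionally conserve B31/W; the coelacanth group
  carries the longer B5-10 PKPDFM block.

Divergence is a per-position substitution probability toward the
uniform composition; insertions/deletions are off by default, matching
the well-defined size of real KRAB domains, so sampled catalogs live on
the fixed coordinate frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    AA_INDEX,
    AMINO_ACIDS,
    Catalog,
    CatalogEntry,
    FRAME_AB,
    KrabCoordinate,
    KrabSequence,
    map_alignment_to_coordinates,
)
from .errors import ValidationError
from .geometry import ResidueCoords
from .mutagen import assemble_hybrid

A32 = KrabCoordinate("A", 32)

#: Consensus mass at a planted motif position (the tall logo letters).
DEFAULT_CONSENSUS_WEIGHT = 0.9

#: Consensus mass at ordinary scaffold positions (moderate conservation).
SCAFFOLD_WEIGHT = 0.5

#: Species pool used when a catalog spec does not name one.
DEFAULT_SPECIES_POOL = (
    "Homo sapiens",
    "Mus musculus",
    "Latimeria chalumnae",
    "Mytilus galloprovincialis",
    "Danio rerio",
    "Monodelphis domestica",
    "Protopterus annectens",
    "Strongylocentrotus purpuratus",
)

_SCAFFOLD_SEED = 20220119
_GROUP_REDRAW_FRACTION = 0.3

#: Hallmark motifs per group, (coordinate string -> residue).
_MOTIFS: Dict[str, Dict[str, str]] = {
    "hs_mKRAB": {
        "A7": "D", "A8": "V", "A31": "V", "A32": "M", "A33": "L", "A34": "E",
        "B13": "L", "B14": "E", "B19": "P", "B20": "W",
    },
    "PRDM9_ortho": {
        "A7": "D", "A8": "I", "A31": "I", "A33": "K", "A34": "R",
        "B7": "P", "B9": "F", "B10": "M", "B31": "W",
    },
    "SSX_ortho": {
        "A7": "D", "A8": "I", "A31": "L", "A33": "K", "A34": "R",
        "B7": "P", "B9": "F", "B10": "M",
    },
    "lcha_ZNF": {
        "A7": "D", "A8": "I", "A31": "V", "A33": "K", "A34": "E",
        "B5": "P", "B6": "K", "B7": "P", "B8": "D", "B9": "F", "B10": "M",
    },
}

#: Groups whose generators never emit at A32 (the ancestral gap).
_AKRAB_GROUPS = ("PRDM9_ortho", "SSX_ortho", "lcha_ZNF")


@dataclass
class SubgroupGenerator:
    """Per-position residue distributions of one KRAB subgroup.

    ``consensus`` maps emitted coordinates to their consensus residue;
    coordinates absent from it (A32 for ancestral groups) are never
    emitted.  ``weights`` can override the consensus mass per position.
    """

    name: str
    consensus: Dict[KrabCoordinate, str]
    consensus_weight: float = DEFAULT_CONSENSUS_WEIGHT
    weights: Dict[KrabCoordinate, float] = field(default_factory=dict)

    def emits_at(self, coord: KrabCoordinate) -> bool:
        return coord in self.consensus

    def distribution(self, coord: KrabCoordinate, divergence: float = 0.0) -> np.ndarray:
        """Sampling distribution over the 20 residues at one position.

        The base profile puts the consensus mass on the planted residue
        and spreads the rest uniformly; divergence mixes the whole
        profile toward uniform.
        """
        if not 0.0 <= divergence <= 1.0:
            raise ValidationError("divergence must be in [0, 1]")
        if coord not in self.consensus:
            raise ValidationError(f"{self.name} never emits at {coord}")
        w = self.weights.get(coord, self.consensus_weight)
        base = np.full(20, (1.0 - w) / 20.0)
        base[AA_INDEX[self.consensus[coord]]] += w
        return (1.0 - divergence) * base + divergence / 20.0

    def consensus_row(self) -> str:
        """The consensus as a gapped row over the full frame."""
        return "".join(self.consensus.get(c, "-") for c in FRAME_AB)

    def sample_row(self, rng: np.random.Generator, divergence: float = 0.0) -> str:
        out = []
        for coord in FRAME_AB:
            if coord not in self.consensus:
                out.append("-")
                continue
            dist = self.distribution(coord, divergence)
            out.append(AMINO_ACIDS[rng.choice(20, p=dist)])
        return "".join(out)


def builtin_generators() -> Dict[str, SubgroupGenerator]:
    """The four built-in subgroup generators, bit-reproducible.

    A scaffold consensus shared by all groups is drawn once from a fixed
    seed; each group redraws a fixed ~30% subset of positions with its
    own seed (so groups are related but separable), then the hallmark
    motifs overwrite their positions and ancestral groups drop A32.
    """
    master = np.random.default_rng(_SCAFFOLD_SEED)
    scaffold = {c: AMINO_ACIDS[master.integers(20)] for c in FRAME_AB}
    generators: Dict[str, SubgroupGenerator] = {}
    for gi, name in enumerate(("hs_mKRAB",) + _AKRAB_GROUPS):
        rng = np.random.default_rng(_SCAFFOLD_SEED + 1 + gi)
        consensus = dict(scaffold)
        n_redraw = int(round(_GROUP_REDRAW_FRACTION * len(FRAME_AB)))
        redraw_idx = rng.choice(len(FRAME_AB), size=n_redraw, replace=False)
        for j in redraw_idx:
            consensus[FRAME_AB[j]] = AMINO_ACIDS[rng.integers(20)]
        weights = {c: SCAFFOLD_WEIGHT for c in consensus}
        for coord_str, res in _MOTIFS[name].items():
            c = KrabCoordinate.from_string(coord_str)
            consensus[c] = res
            weights[c] = DEFAULT_CONSENSUS_WEIGHT
        if name in _AKRAB_GROUPS:
            consensus.pop(A32, None)
            weights.pop(A32, None)
        generators[name] = SubgroupGenerator(name=name, consensus=consensus,
                                             weights=weights)
    return generators


@dataclass
class SyntheticCatalogSpec:
    """Reproducible recipe for a sampled catalog."""

    n_per_group: int
    divergence: float = 0.1
    seed: int = 1072
    species_pool: Sequence[str] = DEFAULT_SPECIES_POOL
    duplicate_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValidationError("duplicate_rate must be in [0, 1)")
        if not self.species_pool:
            raise ValidationError("species_pool must be non-empty")


def sample_catalog(
    spec: SyntheticCatalogSpec,
    generators: Optional[Mapping[str, SubgroupGenerator]] = None,
) -> Tuple[Catalog, Dict[str, str]]:
    """Draw a labeled catalog from the generators.

    Each entry draws a species from the pool; with probability
    ``duplicate_rate`` a verbatim copy of the entry is re-emitted under
    the same species (exercising within-species deduplication).
    Returns the catalog and the id -> generator-name truth labels.
    """
    gens = dict(generators) if generators is not None else builtin_generators()
    rng = np.random.default_rng(spec.seed)
    entries: List[CatalogEntry] = []
    truth: Dict[str, str] = {}
    for name in gens:
        gen = gens[name]
        for i in range(spec.n_per_group):
            row = gen.sample_row(rng, spec.divergence)
            species = str(rng.choice(np.asarray(spec.species_pool, dtype=object)))
            entry_id = f"{name}_{i:04d}"
            seq = map_alignment_to_coordinates(
                row, FRAME_AB, source_id=entry_id, species=species
            )
            entries.append(
                CatalogEntry(id=entry_id, species=species, domain_seq=seq,
                             subgroup=name if name in
                             ("PRDM9_ortho", "SSX_ortho", "lcha_ZNF", "hs_mKRAB")
                             else "unknown")
            )
            truth[entry_id] = name
            if spec.duplicate_rate > 0 and rng.random() < spec.duplicate_rate:
                dup_id = f"{entry_id}_dup"
                dup_seq = map_alignment_to_coordinates(
                    row, FRAME_AB, source_id=dup_id, species=species
                )
                entries.append(
                    CatalogEntry(id=dup_id, species=species, domain_seq=dup_seq,
                                 subgroup=entries[-1].subgroup)
                )
                truth[dup_id] = name
    return Catalog(entries), truth


def alignments_by_group(
    catalog: Catalog, labels: Mapping[str, str],
    columns: Sequence[KrabCoordinate] = FRAME_AB,
) -> Dict[str, List[str]]:
    """Gapped rows over the frame, grouped by label (for logos/counts)."""
    out: Dict[str, List[str]] = {}
    for entry in catalog:
        out.setdefault(labels[entry.id], []).append(entry.domain_seq.to_aligned(columns))
    return out


# ----------------------------------------------------------------------
# Wild-type stand-ins for the mutagenesis roadmap
# ----------------------------------------------------------------------

#: Residues forced onto the group consensus for each synthetic stand-in.
_STANDIN_OVERRIDES: Dict[str, Tuple[str, Dict[str, str]]] = {
    # ZNF10-like modern A domain: FVD at A10-12 (the ZNF10Am1 target),
    # L20/V27 (the residues the roadmap transplants), VMLE at A31-34.
    "ZNF10-A": ("hs_mKRAB", {
        "A9": "F", "A10": "F", "A11": "V", "A12": "D",
        "A20": "L", "A27": "V",
    }),
    # PRDM9-like ancestral A domain: SIY at A10-12, S9/M20/R27 wild-type
    # residues, gap-KR over A32-A34.
    "PRDM9-A": ("PRDM9_ortho", {
        "A9": "S", "A10": "S", "A11": "I", "A12": "Y",
        "A20": "M", "A27": "R",
    }),
    "ZNF10-B": ("hs_mKRAB", {}),
    "PRDM9-B": ("PRDM9_ortho", {}),
}


def reference_stand_ins() -> Dict[str, KrabSequence]:
    """Synthetic wild-type domains for the construct roadmap.

    These are generator-consensus sequences with the roadmap-relevant
    residues forced, NOT the database accessions; they are synthetic
    stand-ins so the package needs no fetch step.  A-domain stand-ins
    cover A1-A42 (PRDM9-A leaves A32 unmapped), B stand-ins cover
    B1-B35.
    """
    gens = builtin_generators()
    out: Dict[str, KrabSequence] = {}
    for name, (group, overrides) in _STANDIN_OVERRIDES.items():
        consensus = dict(gens[group].consensus)
        for coord_str, res in overrides.items():
            consensus[KrabCoordinate.from_string(coord_str)] = res
        sub = "B" if name.endswith("-B") else "A"
        row = "".join(
            consensus.get(c, "-") if c.subdomain == sub else "-" for c in FRAME_AB
        )
        out[name] = map_alignment_to_coordinates(
            row, FRAME_AB, source_id=name, species="Homo sapiens"
        )
    return out


def hybrid_construct(a_name: str, b_name: str = "ZNF10-B") -> KrabSequence:
    """Convenience: stand-in A domain fused to a stand-in B domain."""
    stand_ins = reference_stand_ins()
    return assemble_hybrid(stand_ins[a_name], stand_ins[b_name])


# ----------------------------------------------------------------------
# Helix fixtures
# ----------------------------------------------------------------------

def ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    with_cb: bool = True,
    cb_offset: float = 1.5,
    phase_deg: float = 0.0,
    start_index: int = 1,
) -> List[ResidueCoords]:
    """CA (and radial CB) coordinates of an ideal helix about +z.

    Residue k sits at angle phase + k*twist and height k*rise; the CB is
    placed radially outward, so CA->CB azimuths advance by exactly the
    twist per residue -- the analytic ground truth for register-shift
    measurements.
    """
    if n_res < 1:
        raise ValidationError("ideal_helix needs n_res >= 1")
    out: List[ResidueCoords] = []
    for k in range(n_res):
        theta = math.radians(phase_deg + k * twist)
        ca = np.array([radius * math.cos(theta), radius * math.sin(theta), k * rise])
        cb = None
        if with_cb:
            cb = np.array([
                (radius + cb_offset) * math.cos(theta),
                (radius + cb_offset) * math.sin(theta),
                k * rise,
            ])
        out.append(ResidueCoords(index=start_index + k,
                                 name="ALA" if with_cb else "GLY", ca=ca, cb=cb))
    return out


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to ``direction`` (Rodrigues)."""
    d = np.asarray(direction, float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValidationError("direction must be non-zero")
    d = d / norm
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    s = np.linalg.norm(v)
    c = float(np.dot(z, d))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def composite_structure(
    segments: Sequence[Tuple[int, Sequence[float]]],
    coil_length: int = 4,
    coil_spacing: float = 3.5,
    helix_kwargs: Optional[dict] = None,
) -> List[ResidueCoords]:
    """Helices along given directions joined by straight coil linkers.

    ``segments`` lists (n_residues, axis direction) pairs; consecutive
    helices are connected by ``coil_length`` glycine CAs spaced
    ``coil_spacing`` A apart along the next helix direction (too
    stretched to satisfy the helix criteria).  Inter-axis angles equal
    the angles between the requested directions -- the constructed
    ground truth for L-shaped or three-helix bodies.
    """
    if not segments:
        raise ValidationError("composite_structure needs at least one segment")
    out: List[ResidueCoords] = []
    origin = np.zeros(3)
    index = 1
    for n_res, direction in segments:
        if n_res < 1:
            raise ValidationError("helix segments must have n_res >= 1")
        R = _rotation_to(np.asarray(direction, float))
        helix = ideal_helix(n_res, start_index=index, **(helix_kwargs or {}))
        base = helix[0].ca.copy()
        for res in helix:
            res.ca = R @ (res.ca - base) + origin
            if res.cb is not None:
                res.cb = R @ (res.cb - base) + origin
        out.extend(helix)
        index += n_res
        end = out[-1].ca
        d = R @ np.array([0.0, 0.0, 1.0])
        for k in range(1, coil_length + 1):
            out.append(ResidueCoords(index=index, name="GLY",
                                     ca=end + k * coil_spacing * d))
            index += 1
        origin = out[-1].ca + coil_spacing * d
    # Trim the trailing coil after the last helix.
    return out[:-coil_length] if coil_length else out
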