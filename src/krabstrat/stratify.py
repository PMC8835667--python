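"""Subgroup stratification: cross-scoring, clamped -log10 transforms,
group summaries, rank tests, curation filters and deduplication.

E-values weaker than the curation floor (default 0.01) are clamped to
the floor before the -log10 transform, so no transformed score falls
below 2.0; clamped cells are flagged so that report renderers can print
them as "<2".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import Catalog, CatalogEntry
from .errors import CalibrationError, DataError, ValidationError
from .hmm import ProfileHMM, evalue, forward_score

#: Maximal total-score deviation treated as a tie when assigning subgroups.
TIE_EPS = 1e-12


def clamp_neglog10(evalue_: float, floor_evalue: float = 0.01) -> Tuple[float, bool]:
    """Clamped -log10 transform of an E-value.

    E-values at or above the floor are set to the floor before the
    transform (E = 0.01 -> 2.0, flagged as clamped).
    """
    if not evalue_ > 0:
        raise ValidationError(f"E-value must be positive, got {evalue_}")
    if not floor_evalue > 0:
        raise ValidationError("floor_evalue must be positive")
    if evalue_ >= floor_evalue:
        return (-math.log10(floor_evalue), True)
    return (-math.log10(evalue_), False)


@dataclass
class ScoreMatrix:
    """Clamped -log10 E-values of catalog entries against a model panel."""

    values: pd.DataFrame          # rows: entry ids, columns: model names
    clamp_flags: pd.DataFrame     # same shape, bool
    floor_evalue: float = 0.01

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.clamp_flags.index) or \
           not self.values.columns.equals(self.clamp_flags.columns):
            raise ValidationError("values and clamp_flags must be aligned")
        floor_val = -math.log10(self.floor_evalue)
        if (self.values.values < floor_val - 1e-12).any():
            raise ValidationError(f"clamped matrix contains values below {floor_val}")

    def row(self, entry_id: str) -> pd.Series:
        return self.values.loc[entry_id]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "id"
        out.to_csv(path, sep="\t")

    def render(self) -> pd.DataFrame:
        """Human-readable table printing clamped cells as "<2"-style."""
        floor_txt = f"<{-math.log10(self.floor_evalue):g}"
        return self.values.where(~self.clamp_flags, floor_txt)


def cross_score(
    catalog: Catalog,
    panel: Mapping[str, ProfileHMM],
    n_db: Optional[int] = None,
    floor_evalue: float = 0.01,
) -> ScoreMatrix:
    """Score every catalog entry against every panel model.

    ``n_db`` defaults to the catalog size, mirroring database-conditional
    E-values.  All panel models must be calibrated.
    """
    if not panel:
        raise ValidationError("empty model panel")
    for name, model in panel.items():
        if not model.calibrated:
            raise CalibrationError(f"panel model {name!r} is not calibrated")
    if n_db is None:
        n_db = max(len(catalog), 1)
    ids = catalog.ids()
    names = list(panel)
    vals = np.empty((len(ids), len(names)))
    flags = np.empty((len(ids), len(names)), dtype=bool)
    for i, entry in enumerate(catalog):
        seq = entry.domain_seq.residues
        for j, name in enumerate(names):
            ev = evalue(panel[name], forward_score(panel[name], seq), n_db=n_db)
            vals[i, j], flags[i, j] = clamp_neglog10(ev, floor_evalue)
    return ScoreMatrix(
        values=pd.DataFrame(vals, index=ids, columns=names),
        clamp_flags=pd.DataFrame(flags, index=ids, columns=names),
        floor_evalue=floor_evalue,
    )


def assign_subgroup(entry_scores: pd.Series) -> Tuple[str, float]:
    """Best-model label and its margin over the runner-up.

    A strict tie at the top (including the all-clamped row) yields
    ("unknown", 0.0) -- tied scores never assign a subgroup.
    """
    if len(entry_scores) == 0:
        raise ValidationError("need at least one model column")
    if len(entry_scores) == 1:
        return (str(entry_scores.index[0]), 0.0)
    order = entry_scores.sort_values(ascending=False)
    best, second = float(order.iloc[0]), float(order.iloc[1])
    if best - second < TIE_EPS:
        return ("unknown", 0.0)
    return (str(order.index[0]), best - second)


@dataclass
class GroupSummary:
    """Median and range of one (truth group, model) score cell."""

    group: str
    model: str
    count: int
    median: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValidationError("group summary needs count > 0")
        if not self.min <= self.median <= self.max:
            raise ValidationError("min <= median <= max violated")


def summarize_groups(
    matrix: ScoreMatrix, truth_labels: Mapping[str, str]
) -> List[GroupSummary]:
    """Per-(group, model) count / median / range of clamped scores."""
    missing = [i for i in matrix.values.index if i not in truth_labels]
    if missing:
        raise DataError(f"entries without truth label: {missing[:5]}")
    out: List[GroupSummary] = []
    groups = sorted(set(truth_labels[i] for i in matrix.values.index))
    for group in groups:
        idx = [i for i in matrix.values.index if truth_labels[i] == group]
        sub = matrix.values.loc[idx]
        for model in matrix.values.columns:
            col = sub[model]
            out.append(
                GroupSummary(
                    group=group,
                    model=str(model),
                    count=len(col),
                    median=float(col.median()),
                    min=float(col.min()),
                    max=float(col.max()),
                )
            )
    return out


def summary_table(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = [
        {
            "group": s.group,
            "model": s.model,
            "count": s.count,
            "median": s.median,
            "min": s.min,
            "max": s.max,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Two-sided Wilcoxon-Mann-Whitney test
# ----------------------------------------------------------------------

def _rank_sum_u(values_a: Sequence[float], values_b: Sequence[float]) -> Tuple[float, np.ndarray]:
    """U statistic of sample a plus the pooled average ranks."""
    pooled = np.concatenate([np.asarray(values_a, float), np.asarray(values_b, float)])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # average rank, 1-based
        i = j + 1
    n_a = len(values_a)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    return u_a, ranks


def _exact_p(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Exact two-sided p by enumerating all group assignments.

    Two-sidedness is by deviation of U from its mean: p is the fraction
    of assignments whose |U - mu| is at least the observed one.
    """
    n_a, n_b = len(values_a), len(values_b)
    u_obs, ranks = _rank_sum_u(values_a, values_b)
    mu = n_a * n_b / 2.0
    obs_dev = abs(u_obs - mu)
    n = n_a + n_b
    offset = n_a * (n_a + 1) / 2.0
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mu) >= obs_dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


def _approx_p(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n_a, n_b = len(values_a), len(values_b)
    u_obs, ranks = _rank_sum_u(values_a, values_b)
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(np.asarray(list(values_a) + list(values_b), float),
                          return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    return float(min(1.0, max(0.0, 2.0 * norm.sf(max(z, 0.0)))))


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration when both samples have at most 8 values, normal
    approximation (tie- and continuity-corrected) otherwise.  Two equal
    constant samples give p = 1 by convention.
    """
    if len(values_a) < 1 or len(values_b) < 1:
        raise ValidationError("both samples need at least one value")
    pooled = list(values_a) + list(values_b)
    if all(v == pooled[0] for v in pooled):
        return 1.0
    if len(values_a) <= 8 and len(values_b) <= 8:
        return _exact_p(values_a, values_b)
    return _approx_p(values_a, values_b)


def pairwise_group_tests(
    matrix: ScoreMatrix, truth_labels: Mapping[str, str], model: str
) -> pd.DataFrame:
    """All pairwise WMW p-values between truth groups for one model column."""
    groups = sorted(set(truth_labels.values()))
    by_group = {
        g: matrix.values.loc[[i for i in matrix.values.index if truth_labels[i] == g], model]
        for g in groups
    }
    out = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for g1, g2 in itertools.combinations(groups, 2):
        p = compare_groups(by_group[g1].tolist(), by_group[g2].tolist())
        out.loc[g1, g2] = p
        out.loc[g2, g1] = p
    return out


# ----------------------------------------------------------------------
# Curation
# ----------------------------------------------------------------------

@dataclass
class CurationReport:
    """Which entries a curation step removed, and why."""

    threshold: float
    model: str
    removed: Dict[str, float] = field(default_factory=dict)  # id -> E-value
    merged: Dict[str, List[str]] = field(default_factory=dict)  # kept id -> merged ids


def curate_filter(
    catalog: Catalog,
    model: ProfileHMM,
    keep_below: float,
    n_db: Optional[int] = None,
) -> Tuple[Catalog, CurationReport]:
    """Retain entries scoring E < ``keep_below`` against ``model``.

    The boundary is exclusive: an entry at exactly the threshold is
    removed, matching "remove E-values >= threshold" semantics.
    """
    if not model.calibrated:
        raise CalibrationError("curation model must be calibrated")
    if n_db is None:
        n_db = max(len(catalog), 1)
    report = CurationReport(threshold=keep_below, model=model.name)
    kept = []
    for entry in catalog:
        ev = evalue(model, forward_score(model, entry.domain_seq.residues), n_db=n_db)
        if ev < keep_below:
            kept.append(entry)
        else:
            report.removed[entry.id] = ev
    return Catalog(kept), report


def dedup_within_species(catalog: Catalog) -> Tuple[Catalog, Dict[str, List[str]]]:
    """Collapse identical domain sequences within each species.

    The first entry (catalog order) is kept; the ids merged into it are
    returned.  Identical sequences in different species are untouched.
    """
    kept: List[CatalogEntry] = []
    merged: Dict[str, List[str]] = {}
    seen: Dict[Tuple[str, str], str] = {}  # (species, residues) -> kept id
    for entry in catalog:
        key = (entry.species, entry.domain_seq.residues)
        if key in seen:
            merged.setdefault(seen[key], []).append(entry.id)
        else:
            seen[key] = entry.id
            kept.append(entry)
    return Catalog(kept), merged
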