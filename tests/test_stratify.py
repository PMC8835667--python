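"""Clamping, cross-scoring, assignment, summaries, rank test, curation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from krabstrat.core import Catalog
from krabstrat.errors import CalibrationError, ValidationError
from krabstrat.hmm import build_profile, calibrate_evd
from krabstrat.stratify import (
    ScoreMatrix,
    assign_subgroup,
    clamp_neglog10,
    compare_groups,
    cross_score,
    curate_filter,
    dedup_within_species,
    summarize_groups,
)
from krabstrat.synth import (
    SyntheticCatalogSpec,
    alignments_by_group,
    sample_catalog,
)

from _oracles import exact_wmw_p_by_enumeration


class TestClamping:
    def test_floor_evalue_maps_to_exactly_two(self):
        assert clamp_neglog10(0.01) == (2.0, True)

    def test_strong_evalue_passes_through(self):
        value, clamped = clamp_neglog10(1e-10)
        assert value == pytest.approx(10.0)
        assert not clamped

    def test_weak_evalue_clamps_to_floor(self):
        assert clamp_neglog10(0.5) == (2.0, True)

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ValidationError):
            clamp_neglog10(0.0)

    def test_custom_floor(self):
        value, clamped = clamp_neglog10(1e-3, floor_evalue=1e-4)
        assert (value, clamped) == (4.0, True)


@pytest.fixture(scope="module")
def scored_panel():
    """Small catalog cross-scored against per-group models."""
    spec = SyntheticCatalogSpec(n_per_group=8, divergence=0.1, seed=21)
    catalog, truth = sample_catalog(spec)
    groups = alignments_by_group(catalog, truth)
    panel = {
        name: calibrate_evd(build_profile(rows, name=name), n_samples=120, seed=21)
        for name, rows in sorted(groups.items())
    }
    matrix = cross_score(catalog, panel)
    return catalog, truth, panel, matrix


class TestCrossScore:
    def test_matrix_shape_and_floor(self, scored_panel):
        catalog, _, panel, matrix = scored_panel
        assert matrix.values.shape == (len(catalog), len(panel))
        assert (matrix.values.values >= 2.0 - 1e-12).all()
        assert (matrix.values.values[matrix.clamp_flags.values] == 2.0).all()

    def test_own_model_median_dominates_every_cross_model(self, scored_panel):
        _, truth, panel, matrix = scored_panel
        for group in panel:
            ids = [i for i in matrix.values.index if truth[i] == group]
            own = matrix.values.loc[ids, group].median()
            for other in panel:
                if other != group:
                    assert own > matrix.values.loc[ids, other].median()

    def test_single_entry_single_model(self, scored_panel):
        catalog, _, panel, _ = scored_panel
        one = Catalog([catalog.entries[0]])
        name = next(iter(panel))
        m = cross_score(one, {name: panel[name]})
        assert m.values.shape == (1, 1)

    def test_uncalibrated_panel_rejected(self, scored_panel):
        catalog, truth, _, _ = scored_panel
        rows = alignments_by_group(catalog, truth)["hs_mKRAB"]
        raw = build_profile(rows, name="raw")
        with pytest.raises(CalibrationError):
            cross_score(catalog, {"raw": raw})
        with pytest.raises(ValidationError):
            cross_score(catalog, {})

    def test_deterministic_given_seeds(self, scored_panel):
        catalog, _, panel, matrix = scored_panel
        again = cross_score(catalog, panel)
        pd.testing.assert_frame_equal(matrix.values, again.values)


class TestAssignment:
    def test_clear_winner(self):
        label, margin = assign_subgroup(pd.Series({"A": 12.0, "B": 4.0}))
        assert (label, margin) == ("A", 8.0)

    def test_all_clamped_row_is_unknown(self):
        label, margin = assign_subgroup(pd.Series({"A": 2.0, "B": 2.0, "C": 2.0}))
        assert (label, margin) == ("unknown", 0.0)

    def test_synthetic_entries_assigned_to_true_generator(self, scored_panel):
        _, truth, _, matrix = scored_panel
        correct = sum(
            1 for i in matrix.values.index
            if assign_subgroup(matrix.row(i))[0] == truth[i]
        )
        assert correct / len(matrix.values) >= 0.95


class TestSummaries:
    def test_median_and_range_hand_case(self):
        values = pd.DataFrame({"m": [2.0, 3.0, 4.0]}, index=["a", "b", "c"])
        flags = pd.DataFrame({"m": [True, False, False]}, index=["a", "b", "c"])
        matrix = ScoreMatrix(values=values, clamp_flags=flags)
        (s,) = summarize_groups(matrix, {"a": "g", "b": "g", "c": "g"})
        assert (s.count, s.median, s.min, s.max) == (3, 3.0, 2.0, 4.0)

    def test_group_of_one_collapses(self):
        values = pd.DataFrame({"m": [5.0]}, index=["a"])
        flags = pd.DataFrame({"m": [False]}, index=["a"])
        (s,) = summarize_groups(ScoreMatrix(values, flags), {"a": "g"})
        assert s.median == s.min == s.max == 5.0

    def test_clamped_cells_render_as_below_floor(self):
        values = pd.DataFrame({"m": [2.0, 9.0]}, index=["a", "b"])
        flags = pd.DataFrame({"m": [True, False]}, index=["a", "b"])
        rendered = ScoreMatrix(values, flags).render()
        assert rendered.loc["a", "m"] == "<2"
        assert rendered.loc["b", "m"] == 9.0


class TestCompareGroups:
    def test_identical_samples_give_p_one(self):
        assert compare_groups([1, 2, 3], [1, 2, 3]) == 1.0

    def test_disjoint_hand_case_two_over_seventy(self):
        assert compare_groups([1, 2, 3, 4], [10, 11, 12, 13]) == pytest.approx(2 / 70)

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 2), (5, 4), (8, 8)])
    def test_exact_branch_matches_independent_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            a = rng.normal(size=n_a).tolist()
            b = rng.normal(size=n_b).tolist()
            assert compare_groups(a, b) == pytest.approx(
                exact_wmw_p_by_enumeration(a, b), abs=1e-12
            )

    def test_exact_branch_matches_scipy_on_untied_inputs(self):
        rng = np.random.default_rng(5)
        for n_a, n_b in [(4, 4), (6, 5), (8, 8)]:
            a = rng.permutation(100)[:n_a].tolist()
            b = (rng.permutation(100)[:n_b] + 200).tolist()
            b = rng.permutation(np.concatenate([a, b]))  # mix them up
            a, b = b[:n_a].tolist(), b[n_a:].tolist()
            expected = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert compare_groups(a, b) == pytest.approx(expected, abs=1e-12)

    def test_approximation_close_to_exact_at_boundary_size(self):
        """Normal approximation stays within 0.02 of the exact value."""
        rng = np.random.default_rng(17)
        from krabstrat.stratify import _approx_p, _exact_p

        for _ in range(25):
            pool = rng.permutation(40)[:16]
            a, b = pool[:8].tolist(), pool[8:].tolist()
            assert abs(_approx_p(a, b) - _exact_p(a, b)) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([], [1.0])

    def test_separated_synthetic_groups_are_significant(self, scored_panel):
        _, truth, panel, matrix = scored_panel
        model = "hs_mKRAB"
        own = [matrix.values.loc[i, model] for i in matrix.values.index
               if truth[i] == model]
        other = [matrix.values.loc[i, model] for i in matrix.values.index
                 if truth[i] == "PRDM9_ortho"]
        assert compare_groups(own, other) < 0.01


class TestCuration:
    def test_boundary_evalue_is_removed(self, scored_panel):
        catalog, _, panel, _ = scored_panel
        model = panel["hs_mKRAB"]
        kept, report = curate_filter(catalog, model, keep_below=0.01)
        for entry_id, ev in report.removed.items():
            assert ev >= 0.01
        assert len(kept) + len(report.removed) == len(catalog)

    def test_strict_pass_removes_weak_entries(self, scored_panel):
        catalog, truth, panel, _ = scored_panel
        model = panel["hs_mKRAB"]
        kept, report = curate_filter(catalog, model, keep_below=1e-10)
        # the model's own subgroup survives a strict pass better than others
        kept_own = sum(1 for i in kept.ids() if truth[i] == "hs_mKRAB")
        assert kept_own > 0
        assert len(kept) < len(catalog)

    def test_empty_catalog_passes_through(self, scored_panel):
        _, _, panel, _ = scored_panel
        kept, report = curate_filter(Catalog([]), panel["hs_mKRAB"], 0.01)
        assert len(kept) == 0 and not report.removed

    def test_idempotent(self, scored_panel):
        catalog, _, panel, _ = scored_panel
        model = panel["SSX_ortho"]
        once, _ = curate_filter(catalog, model, keep_below=0.01)
        twice, report = curate_filter(once, model, keep_below=0.01, n_db=len(catalog))
        # n_db pinned to the first run's size: identical E-values, no removals
        assert twice.ids() == once.ids()


class TestDedup:
    def test_same_species_duplicates_collapse(self, small_catalog):
        catalog, _ = small_catalog
        entry = catalog.entries[0]
        from krabstrat.core import CatalogEntry

        dup = CatalogEntry(id="copy", species=entry.species,
                           domain_seq=entry.domain_seq, subgroup=entry.subgroup)
        merged_catalog, merged = dedup_within_species(Catalog([entry, dup]))
        assert len(merged_catalog) == 1
        assert merged == {entry.id: ["copy"]}

    def test_cross_species_duplicates_kept(self, small_catalog):
        catalog, _ = small_catalog
        entry = catalog.entries[0]
        from krabstrat.core import CatalogEntry, KrabSequence

        other_seq = KrabSequence(entry.domain_seq.residues,
                                 dict(entry.domain_seq.coord_map),
                                 species="Danio rerio")
        other = CatalogEntry(id="other", species="Danio rerio", domain_seq=other_seq)
        merged_catalog, merged = dedup_within_species(Catalog([entry, other]))
        assert len(merged_catalog) == 2 and not merged

    def test_three_entries_two_identical(self, small_catalog):
        catalog, _ = small_catalog
        from krabstrat.core import CatalogEntry

        e0, e1 = catalog.entries[0], catalog.entries[1]
        dup = CatalogEntry(id="dup0", species=e0.species, domain_seq=e0.domain_seq)
        merged_catalog, _ = dedup_within_species(Catalog([e0, e1, dup]))
        assert len(merged_catalog) == 2
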