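"""Three-tier selection filters and the multi-generation campaign driver."""

import numpy as np
import pandas as pd
import pytest

from mabckit.backcross_sim import GenotypeMatrix, cross, genotype_plants, true_rpg
from mabckit.exceptions import CampaignHalt, ConfigurationError
from mabckit.rpg_report import compute_rpg
from mabckit.selection_engine import (
    CampaignConfig,
    SelectionRoles,
    background_select,
    drop_fixed_markers,
    foreground_select,
    rank_by_rpg,
    recombinant_select,
    run_campaign,
)


def matrix_from(rows: dict[str, str], markers: list[str]) -> GenotypeMatrix:
    frame = pd.DataFrame(
        [list(calls) for calls in rows.values()],
        index=list(rows),
        columns=markers,
    )
    return GenotypeMatrix(frame)


FG = ["RM493", "RM3412b"]


class TestForegroundSelect:
    def test_keeps_only_double_heterozygotes(self):
        m = matrix_from(
            {"p1": "HH", "p2": "AH", "p3": "HA", "p4": "HB", "p5": "H-"}, FG
        )
        assert foreground_select(m, FG) == ["p1"]

    def test_missing_call_disqualifies(self):
        m = matrix_from({"p1": "H-"}, FG)
        assert foreground_select(m, FG) == []

    def test_absent_marker_is_a_configuration_error(self):
        m = matrix_from({"p1": "H"}, ["RM493"])
        with pytest.raises(ConfigurationError, match="RM3412b"):
            foreground_select(m, FG)

    def test_bc1_retention_near_one_half(self, f1, founders, genetic_map, full_panel):
        recipient, _ = founders
        rng = np.random.default_rng(5)
        progeny = cross(f1, recipient, 300, genetic_map, rng)
        matrix = genotype_plants(progeny, full_panel.subset(FG))
        kept = foreground_select(matrix, FG)
        # binomial(300, ~0.49) 99% bounds, the two markers being ~2.8 cM apart
        assert 120 <= len(kept) <= 175


class TestRecombinantSelect:
    def test_requires_recipient_homozygote_at_flank(self):
        m = matrix_from({"p1": "A", "p2": "H", "p3": "B", "p4": "-"}, ["RM10825"])
        assert recombinant_select(m, {"RM10825": "A"}) == ["p1"]

    def test_empty_requirement_keeps_all(self):
        m = matrix_from({"p1": "A", "p2": "H"}, ["RM10825"])
        assert recombinant_select(m, {}) == ["p1", "p2"]

    def test_absent_flank_marker_is_a_configuration_error(self):
        m = matrix_from({"p1": "A"}, ["RM10825"])
        with pytest.raises(ConfigurationError, match="RM10694"):
            recombinant_select(m, {"RM10694": "A"})

    def test_retained_fraction_matches_crossover_frequency(
        self, f1, founders, genetic_map, full_panel
    ):
        from mabckit.backcross_sim import haldane_recomb_fraction

        recipient, _ = founders
        rng = np.random.default_rng(9)
        progeny = cross(f1, recipient, 3000, genetic_map, rng)
        matrix = genotype_plants(progeny, full_panel.subset([*FG, "RM10825"]))
        fg = foreground_select(matrix, FG)
        rc = recombinant_select(matrix.subset_plants(fg), {"RM10825": "A"})
        d_morgans = (13306166 - 12264091) * 4.0 / 1e8
        expected = haldane_recomb_fraction(d_morgans)
        observed = len(rc) / len(fg)
        se = np.sqrt(expected * (1 - expected) / len(fg))
        assert abs(observed - expected) <= 3 * se


class TestBackgroundSelect:
    def test_all_recipient_plant_dominates_single_heterozygote(self):
        m = matrix_from({"p1": "AAAA", "p2": "AAAH"}, list("WXYZ"))
        assert background_select(m, list("WXYZ"), 1) == ["p1"]

    def test_toy_matrix_ranking_equals_brute_force_enumeration(self, toy):
        markers = toy.marker_names

        def key(pid):
            s = compute_rpg(toy.calls_for(pid), plant_id=pid)
            return (-s.percent_R, -s.percent_A, pid)

        brute = sorted(toy.plant_ids, key=key)
        ranked = list(rank_by_rpg(toy, markers)["plant_id"])
        assert ranked == brute
        assert background_select(toy, markers, 2) == brute[:2]

    def test_tie_breaks_by_percent_A_then_id(self, toy):
        # P3 and P4 tie on %R; P4 wins on %A
        ranked = list(rank_by_rpg(toy, toy.marker_names)["plant_id"])
        assert ranked.index("P4") < ranked.index("P3")

    def test_oversized_k_returns_all_candidates(self, toy):
        assert len(background_select(toy, toy.marker_names, 99)) == 4

    def test_empty_candidate_set_warns_and_returns_empty(self, toy):
        empty = toy.subset_plants([])
        assert background_select(empty, toy.marker_names, 2) == []


class TestDropFixedMarkers:
    def test_marker_recipient_homozygous_in_all_selected_is_dropped(self):
        m = matrix_from({"p1": "AH", "p2": "AA"}, ["W", "X"])
        remaining, fixed = drop_fixed_markers(m, ["p1", "p2"], ["W", "X"])
        assert fixed == ["W"]
        assert remaining == ["X"]

    def test_missing_is_uninformative_not_fixed(self):
        m = matrix_from({"p1": "A-", "p2": "A-"}, ["W", "X"])
        remaining, fixed = drop_fixed_markers(m, ["p1", "p2"], ["W", "X"])
        assert fixed == ["W"]
        assert remaining == ["X"]

    def test_all_markers_fixed_leaves_ledger_only(self):
        m = matrix_from({"p1": "AA"}, ["W", "X"])
        remaining, fixed = drop_fixed_markers(m, ["p1"], ["W", "X"])
        assert remaining == []
        # downstream %R computed from the ledger alone
        summary = compute_rpg([], fixed_ledger=len(fixed), plant_id="p1")
        assert summary.percent_R == 100.0

    def test_conservation_of_the_background_panel(self):
        m = matrix_from({"p1": "AHAB"}, list("WXYZ"))
        remaining, fixed = drop_fixed_markers(m, ["p1"], list("WXYZ"))
        assert sorted(remaining + fixed) == list("WXYZ")


def small_config(seed, **overrides) -> CampaignConfig:
    defaults = dict(seed=seed, pop_size=120, n_parents_advanced=2)
    defaults.update(overrides)
    return CampaignConfig(**defaults)


@pytest.fixture(scope="module")
def trace():
    return run_campaign(small_config(2012))


class TestCampaign:
    def test_survivor_sets_are_nested(self, trace):
        for rec in trace.generations:
            assert set(rec.recombinant_ids) <= set(rec.foreground_ids)
            assert len(rec.foreground_ids) <= rec.n_population
            assert set(rec.advanced_ids) <= set(rec.recombinant_ids)

    def test_selection_improves_mean_percent_R(self, trace):
        for rec in trace.generations:
            pool = rec.ranking["percent_R"]
            selected = rec.ranking.set_index("plant_id").loc[
                rec.advanced_ids, "percent_R"
            ]
            assert selected.mean() >= pool.mean()

    def test_fixed_marker_ledger_conserved_each_generation(self, trace):
        n_background = trace.config_summary["n_background_markers"]
        for rec in trace.generations:
            assert len(rec.screened_background) + rec.fixed_ledger == n_background

    def test_selection_does_not_alter_genotype_data(self, trace):
        rec = trace.generations[0]
        before = rec.matrix.frame.copy()
        foreground_select(rec.matrix, trace.config_summary["foreground"])
        background_select(rec.matrix, rec.screened_background, 2)
        assert rec.matrix.frame.equals(before)

    def test_identical_seed_reproduces_identical_trace(self):
        a = run_campaign(small_config(77))
        b = run_campaign(small_config(77))
        assert a.config_summary == b.config_summary
        for ra, rb in zip(a.generations, b.generations):
            assert ra.matrix.frame.equals(rb.matrix.frame)
            assert ra.advanced_ids == rb.advanced_ids
        assert [s.plant_id for s in a.final_summaries] == [
            s.plant_id for s in b.final_summaries
        ]

    def test_final_summaries_cover_the_whole_background_panel(self, trace):
        for s in trace.final_summaries:
            assert s.n_A + s.n_B + s.n_H + s.n_missing == (
                trace.config_summary["n_background_markers"]
            )

    def test_impossible_flank_requirement_halts_with_generation(self):
        roles = SelectionRoles(
            flank_markers_by_generation={1: {"RM10825": "B"}},  # unreachable in a BC
        )
        config = small_config(3, roles=None)
        config.roles.flank_markers_by_generation = roles.flank_markers_by_generation
        with pytest.raises(CampaignHalt) as err:
            run_campaign(config)
        assert err.value.generation == 1
        assert err.value.stage == "recombinant"

    def test_marker_based_percent_R_tracks_true_rpg_with_dense_markers(
        self, genetic_map, full_panel
    ):
        # %R over markers converges to the bp-weighted truth as density grows
        from mabckit.backcross_sim import unselected_backcross_population
        from mabckit.datasets import build_background_panel

        rng = np.random.default_rng(31)
        plants = unselected_backcross_population(60, 1, genetic_map, rng)
        errors = {}
        for n_markers in (48, 480):
            panel = build_background_panel(n_markers)
            matrix = genotype_plants(plants, panel)
            errs = [
                abs(
                    compute_rpg(matrix.calls_for(p.plant_id)).percent_R
                    - true_rpg(p)
                )
                for p in plants
            ]
            errors[n_markers] = np.mean(errs)
        assert errors[480] < errors[48]
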