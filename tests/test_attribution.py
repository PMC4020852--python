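"""Identifiability rules and the boolean attribution logic, verified
against exhaustive truth-table oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest

from lpasig import (SimulationConfig, simulate_attribution_dataset,
                    run_attribution_pipeline)
from lpasig.attribution import (attribute, check_identifiability,
                                collapse_to_genes, derive_receptor_profile)
from lpasig.containers import ReceptorDesign
from lpasig.response import ResponseCalls

LINES = ["PC3", "MDA-MB-231", "MCF-7"]


def calls_from_patterns(patterns: dict[str, tuple[str, ...]]) -> ResponseCalls:
    frame = pd.DataFrame(patterns, index=LINES).T
    return ResponseCalls(frame)


class TestDeriveReceptorProfile:
    def test_thresholding_recovers_lpa_design(self, design):
        # receptor probe fluorescence built so that >100 means present
        fluor = design.presence.astype(float) * 400 + 50
        derived = derive_receptor_profile(fluor, presence_threshold=100.0)
        pd.testing.assert_frame_equal(derived.presence, design.presence)
        assert derived.metadata["presence_threshold"]["PC3"] == 100.0

    def test_zero_threshold_makes_everything_present(self, design):
        fluor = design.presence.astype(float) * 400 + 50
        derived = derive_receptor_profile(fluor, presence_threshold=0.0)
        assert derived.presence.all().all()

    def test_all_below_threshold_gives_empty_design(self, design):
        fluor = design.presence.astype(float) * 400 + 50
        derived = derive_receptor_profile(fluor, presence_threshold=1e6)
        assert not derived.presence.any().any()
        report = check_identifiability(derived)
        assert report.identifiable_receptors() == []

    def test_percentile_default_needs_background(self, design):
        fluor = design.presence.astype(float) * 400 + 10
        with pytest.raises(ValueError, match="background"):
            derive_receptor_profile(fluor)
        rng = np.random.default_rng(0)
        background = pd.DataFrame(rng.uniform(10, 30, (500, 3)),
                                  columns=LINES)
        derived = derive_receptor_profile(fluor, background=background)
        # threshold = 3 x 10th percentile of U(10,30) ~= 36: the
        # 410-level (present) entries clear it, the 10-level ones do not
        pd.testing.assert_frame_equal(derived.presence, design.presence)

    def test_missing_receptor_value_is_an_error(self, design):
        fluor = design.presence.astype(float) * 400 + 50
        fluor.loc["LPA1", "PC3"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            derive_receptor_profile(fluor, presence_threshold=100.0)


class TestIdentifiability:
    def test_lpa_design_statuses(self, design):
        """LPA1/LPA6 identifiable; LPA2 has no negative line; LPA3 only
        one positive line."""
        rep = check_identifiability(design)
        assert rep["LPA1"].status == "identifiable"
        assert rep["LPA6"].status == "identifiable"
        assert rep["LPA2"].status == "no_negative_line"
        assert rep["LPA3"].status == "insufficient_positive_lines"
        assert (rep["LPA1"].n_positive_lines,
                rep["LPA1"].n_negative_lines) == (2, 1)

    def test_statuses_match_brute_force_rules(self, design):
        """Re-derive each status by directly applying the three rules."""
        rep = check_identifiability(design, min_positive=2, min_negative=1)
        patterns = {r: tuple(design.presence.loc[r]) for r in design.receptors}
        for r in design.receptors:
            n_pos = sum(patterns[r])
            n_neg = len(LINES) - n_pos
            duplicated = any(patterns[r] == patterns[s]
                             for s in design.receptors if s != r)
            if n_neg < 1:
                want = "no_negative_line"
            elif n_pos < 2:
                want = "insufficient_positive_lines"
            elif duplicated:
                want = "confounded"
            else:
                want = "identifiable"
            assert rep[r].status.split(":")[0].startswith(want.split(":")[0])

    def test_identical_columns_are_mutually_confounded(self):
        design = ReceptorDesign(pd.DataFrame(
            [[1, 1, 0], [1, 1, 0]], index=["R1", "R2"], columns=LINES))
        rep = check_identifiability(design)
        assert rep["R1"].status == "confounded_with:R2"
        assert rep["R2"].status == "confounded_with:R1"

    def test_single_cell_line_never_identifiable(self):
        design = ReceptorDesign(pd.DataFrame(
            [[1], [0]], index=["R1", "R2"], columns=["only"]))
        assert check_identifiability(design).identifiable_receptors() == []


class TestAttribute:
    def test_fig_rule_up_in_both_positive_not_in_negative(self, design):
        calls = calls_from_patterns({"ps": ("up", "up", "unchanged")})
        res = attribute(calls, design, "LPA1")
        assert res.probe_sets == {"ps"}
        assert res.positive_lines == ["PC3", "MDA-MB-231"]
        assert res.negative_lines == ["MCF-7"]

    def test_up_everywhere_fails_negative_condition(self, design):
        calls = calls_from_patterns({"ps": ("up", "up", "up")})
        assert attribute(calls, design, "LPA1").probe_sets == frozenset()

    def test_exhaustive_truth_table(self, design):
        """All 2^3 up/not-up patterns against the boolean definition."""
        patterns = {f"ps{i}": tuple("up" if b else "unchanged" for b in bits)
                    for i, bits in enumerate(
                        itertools.product([1, 0], repeat=3))}
        res = attribute(calls_from_patterns(patterns), design, "LPA1")
        for name, pat in patterns.items():
            expect = pat[0] == "up" and pat[1] == "up" and pat[2] != "up"
            assert (name in res.probe_sets) == expect

    def test_down_in_negative_line_allowed_unless_strict(self, design):
        calls = calls_from_patterns({"ps": ("up", "up", "down")})
        assert attribute(calls, design, "LPA1").probe_sets == {"ps"}
        strict = attribute(calls, design, "LPA1", strict_negative=True)
        assert strict.probe_sets == frozenset()

    def test_non_identifiable_receptor_requires_force(self, design):
        calls = calls_from_patterns({"ps": ("up", "up", "up")})
        with pytest.raises(ValueError, match="no_negative_line"):
            attribute(calls, design, "LPA2")
        with pytest.warns(UserWarning, match="not receptor-specific"):
            res = attribute(calls, design, "LPA2", force=True)
        assert res.probe_sets == {"ps"}

    def test_unknown_receptor_is_an_error(self, design):
        calls = calls_from_patterns({"ps": ("up", "up", "unchanged")})
        with pytest.raises(KeyError):
            attribute(calls, design, "LPA9")

    def test_line_order_invariance(self, design):
        patterns = {f"ps{i}": pat for i, pat in enumerate(
            itertools.product(["up", "down", "unchanged"], repeat=3))}
        res1 = attribute(calls_from_patterns(patterns), design, "LPA1")
        shuffled = ReceptorDesign(design.presence[list(reversed(LINES))])
        res2 = attribute(calls_from_patterns(patterns), shuffled, "LPA1")
        assert res1.probe_sets == res2.probe_sets

    def test_mirror_down_analysis(self, design):
        calls = calls_from_patterns({"ps": ("down", "down", "unchanged"),
                                     "ps2": ("up", "up", "unchanged")})
        res = attribute(calls, design, "LPA1", direction="down")
        assert res.probe_sets == {"ps"}

    def test_cross_receptor_exclusivity(self, design):
        """No pattern can satisfy both LPA1 and LPA6: their requirements
        conflict on MDA-MB-231 and MCF-7."""
        patterns = {f"ps{i}": pat for i, pat in enumerate(
            itertools.product(["up", "unchanged"], repeat=3))}
        calls = calls_from_patterns(patterns)
        lpa1 = attribute(calls, design, "LPA1").probe_sets
        lpa6 = attribute(calls, design, "LPA6").probe_sets
        assert lpa1 & lpa6 == frozenset()


class TestCollapseToGenes:
    def test_distinct_gene_count(self, design):
        calls = calls_from_patterns({
            "ps1": ("up", "up", "unchanged"),
            "ps2": ("up", "up", "unchanged"),
            "ps3": ("up", "up", "unchanged")})
        res = attribute(calls, design, "LPA1")
        ann = {"ps1": "HBEGF", "ps2": "HBEGF", "ps3": "IL6"}
        collapsed = collapse_to_genes(res, ann)
        assert collapsed.genes == {"HBEGF", "IL6"}
        assert collapsed.n_genes == 2
        assert collapsed.n_unannotated == 0

    def test_unannotated_counted_never_dropped(self, design):
        calls = calls_from_patterns({"ps1": ("up", "up", "unchanged"),
                                     "ps2": ("up", "up", "unchanged")})
        res = attribute(calls, design, "LPA1")
        collapsed = collapse_to_genes(res, {})
        assert collapsed.genes == frozenset()
        assert collapsed.n_unannotated == 2
        assert collapsed.probe_sets == {"ps1", "ps2"}


class TestPlantedRecovery:
    def test_monotone_in_up_threshold(self, design, noiseless_dataset):
        exp, _ = noiseless_dataset
        sizes = []
        for thr in (1.3, 1.6, 1.9, 2.5):
            res, _ = run_attribution_pipeline(exp, design, "LPA1",
                                              up_threshold=thr)
            sizes.append(res.n_probe_sets)
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0  # threshold above the planted effect

    def test_noiseless_recovery_is_exact(self, design, noiseless_dataset):
        exp, truth = noiseless_dataset
        for receptor in ("LPA1", "LPA6"):
            res, _ = run_attribution_pipeline(exp, design, receptor)
            assert res.probe_sets == truth.probe_sets_for(receptor)

    def test_null_effect_recovers_nothing_above_background(self, design):
        cfg = SimulationConfig(design=design, n_genes=300,
                               n_planted_per_receptor=30, effect_size=1.0,
                               noise_cv=0.05, seed=13)
        exp, truth = simulate_attribution_dataset(cfg)
        res, _ = run_attribution_pipeline(exp, design, "LPA1")
        planted = truth.probe_sets_for("LPA1")
        sens = len(res.probe_sets & planted) / len(planted)
        assert sens < 0.05  # no better than background

    def test_context_specific_genes_blocked_by_min_positive(self, design):
        cfg = SimulationConfig(design=design, n_genes=200,
                               n_planted_per_receptor=10, noise_cv=0.0,
                               n_context_specific=9, seed=5)
        exp, truth = simulate_attribution_dataset(cfg)
        res, _ = run_attribution_pipeline(exp, design, "LPA1")
        context_probes = {ps for g in truth.context_specific
                          for ps in truth.gene_probe_sets[g]}
        assert res.probe_sets & context_probes == frozenset()
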