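"""Harmonization pipeline: filters, averaging, normalization invariants."""

import numpy as np
import pandas as pd
import pytest

import wcvr
from wcvr.harmonize import HarmonizationError, ReferenceProportions
from wcvr.peptides import PEPTIDES

from conftest import make_panel


def _random_panel(rng, n_controls=4, n_cases=8, cohort="c0"):
    rows = []
    for i in range(n_controls + n_cases):
        is_case = i >= n_controls
        rows.append(
            {"sample_id": f"{cohort}s{i}", "cohort": cohort,
             "group": "case" if is_case else "control",
             "aao": 40.0 + i if is_case else np.nan,
             "values": rng.lognormal(0, 0.4, 5) * [0.13, 0.15, 0.6, 0.1, 0.02]}
        )
    return make_panel(rows)


class TestZeroFilter:
    def test_identity_without_zeros(self):
        rng = np.random.default_rng(0)
        panel = _random_panel(rng)
        out, removed = wcvr.filter_zero_samples(panel)
        assert removed == 0
        pd.testing.assert_frame_equal(out.data, panel.data)

    def test_removes_exactly_the_zero_bearing_rows(self):
        """230 measurement rows of which 14 carry at least one zero leave
        216 rows behind, mirroring a realistic multi-cohort cleanup."""
        rng = np.random.default_rng(1)
        rows = []
        for i in range(230):
            values = rng.lognormal(0, 0.3, 5) + 0.01
            if i < 14:  # plant one zero in each of the first 14 rows
                values[rng.integers(0, 5)] = 0.0
            rows.append({"sample_id": f"s{i}", "group": "case", "aao": 50.0,
                         "values": values})
        panel = make_panel(rows)
        out, removed = wcvr.filter_zero_samples(panel)
        assert removed == 14
        assert len(out.data) == 216

    def test_all_zero_row_counted_once(self):
        panel = make_panel(
            [{"sample_id": "a", "group": "control", "values": [1, 1, 1, 1, 1]},
             {"sample_id": "b", "group": "control", "values": [0, 0, 0, 0, 0]}]
        )
        out, removed = wcvr.filter_zero_samples(panel)
        assert removed == 1
        assert list(out.data["sample_id"]) == ["a"]


class TestAverageReplicates:
    def test_single_replicate_identity(self):
        rng = np.random.default_rng(2)
        panel = _random_panel(rng)
        out = wcvr.average_replicates(panel)
        np.testing.assert_allclose(out.values, panel.values)

    def test_arithmetic_mean_of_replicates(self):
        panel = make_panel(
            [{"sample_id": "s", "group": "control", "replicate": "r1",
              "values": [10, 1, 1, 1, 1]},
             {"sample_id": "s", "group": "control", "replicate": "r2",
              "values": [20, 3, 1, 1, 1]}]
        )
        out = wcvr.average_replicates(panel)
        assert len(out.data) == 1
        assert out.values[0, 0] == 15.0
        assert out.values[0, 1] == 2.0

    def test_one_row_per_line(self):
        cfg = wcvr.SimulationConfig(n_cohorts=1, n_controls=3, n_cases=10,
                                    n_replicates=3, seed=0)
        panel = wcvr.generate_cohorts(cfg)
        out = wcvr.average_replicates(panel)
        assert len(out.data) == 13

    def test_conflicting_annotations_rejected(self):
        frame = make_panel(
            [{"sample_id": "s", "group": "control", "replicate": "r1",
              "values": [1, 1, 1, 1, 1]}]
        ).data
        bad = pd.concat([frame, frame.assign(group="case", replicate="r2")])
        panel = wcvr.PeptidePanel(bad)
        with pytest.raises(HarmonizationError, match="conflicting"):
            wcvr.average_replicates(panel)


class TestNormalizeToTotal:
    def test_worked_example(self):
        panel = make_panel(
            [{"sample_id": "s", "group": "control", "values": [1, 1, 2, 4, 2]}]
        )
        out = wcvr.normalize_to_total(panel)
        np.testing.assert_allclose(out.values[0], [0.1, 0.1, 0.2, 0.4, 0.2])

    def test_scale_invariance_and_unit_sums(self):
        rng = np.random.default_rng(3)
        panel = _random_panel(rng)
        out = wcvr.normalize_to_total(panel)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)
        scaled = panel.with_values(panel.values * rng.uniform(0.5, 10, (12, 1)))
        np.testing.assert_allclose(
            wcvr.normalize_to_total(scaled).values, out.values, atol=1e-12
        )


class TestControlScaling:
    def test_control_means_equal_one(self):
        rng = np.random.default_rng(4)
        panel = wcvr.normalize_to_total(_random_panel(rng))
        h = wcvr.scale_by_control_means(panel)
        ctrl = h.values[~h.is_case]
        np.testing.assert_allclose(ctrl.mean(axis=0), 1.0, atol=1e-9)

    def test_all_controls_cohort_self_normalizes(self):
        rows = [{"sample_id": f"s{i}", "group": "control",
                 "values": np.random.default_rng(i).uniform(1, 5, 5)}
                for i in range(5)]
        h = wcvr.scale_by_control_means(wcvr.normalize_to_total(make_panel(rows)))
        np.testing.assert_allclose(h.values.mean(axis=0), 1.0, atol=1e-12)

    def test_case_at_control_mean_maps_to_one(self):
        ctrl = [{"sample_id": f"c{i}", "group": "control",
                 "values": [2, 2, 4, 1, 1]} for i in range(3)]
        case = [{"sample_id": "x", "group": "case", "aao": 50.0,
                 "values": [2, 2, 4, 1, 1]}]
        h = wcvr.scale_by_control_means(wcvr.normalize_to_total(make_panel(ctrl + case)))
        np.testing.assert_allclose(h.values[-1], 1.0, atol=1e-12)

    def test_cohort_without_controls_is_an_error(self):
        panel = make_panel(
            [{"sample_id": "x", "cohort": "lonely", "group": "case",
              "aao": 50.0, "values": [1, 1, 1, 1, 1]}]
        )
        with pytest.raises(HarmonizationError, match="lonely"):
            wcvr.scale_by_control_means(panel)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        panel = wcvr.normalize_to_total(_random_panel(rng))
        once = wcvr.scale_by_control_means(panel)
        twice = wcvr.scale_by_control_means(
            wcvr.PeptidePanel(once.data)
        )
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


class TestBiasCancellation:
    """Per-cohort diagonal assay bias cancels through the two-step
    harmonization when each cohort's controls share one relative profile
    (controls differ only in total loading) — the regime the method
    assumes. Cancellation is exact for every ratio biomarker; harmonized
    values agree up to a per-row positive scalar."""

    def _panels(self):
        cfg = wcvr.SimulationConfig(n_cohorts=2, n_controls=4, n_cases=10,
                                    n_replicates=1, noise_cv=0.0, seed=6,
                                    assay_bias=[(1, 1, 1, 1, 1)] * 2)
        biased_cfg = wcvr.SimulationConfig(
            n_cohorts=2, n_controls=4, n_cases=10, n_replicates=1,
            noise_cv=0.0, seed=6,
            assay_bias=[(2.0, 0.5, 1.3, 0.8, 3.0), (0.3, 1.1, 0.9, 2.5, 1.7)],
        )
        return (wcvr.harmonize(wcvr.generate_cohorts(cfg), rescale=False),
                wcvr.harmonize(wcvr.generate_cohorts(biased_cfg), rescale=False))

    def test_scores_exactly_invariant(self):
        plain, biased = self._panels()
        for spec in wcvr.benchmark_specs():
            s1 = wcvr.compute_ratio(spec, plain).scores
            s2 = wcvr.compute_ratio(spec, biased).scores
            np.testing.assert_allclose(s2, s1, rtol=1e-12)

    def test_values_agree_up_to_row_scalar(self):
        plain, biased = self._panels()
        ratio = biased.values / plain.values
        np.testing.assert_allclose(ratio / ratio[:, [0]], 1.0, rtol=1e-10)


class TestReferenceRescaling:
    def test_control_row_maps_to_reference_proportions(self):
        ref = ReferenceProportions.default()
        rng = np.random.default_rng(7)
        h = wcvr.harmonize(_random_panel(rng), rescale=False)
        ones = h.with_values(np.ones_like(h.values))
        out = wcvr.rescale_to_reference(ones, ref)
        np.testing.assert_allclose(
            out.values, np.tile(ref.vector(), (len(out.data), 1)))

    def test_uniform_reference_leaves_ratios_unchanged(self):
        rng = np.random.default_rng(8)
        h = wcvr.harmonize(_random_panel(rng), rescale=False)
        uniform = ReferenceProportions(dict.fromkeys(PEPTIDES, 0.2), "uniform")
        out = wcvr.rescale_to_reference(h, uniform)
        for spec in wcvr.benchmark_specs():
            np.testing.assert_allclose(
                wcvr.compute_ratio(spec, out).scores,
                wcvr.compute_ratio(spec, h).scores, rtol=1e-12,
            )

    def test_short_long_depends_on_rescaling(self):
        rng = np.random.default_rng(9)
        h = wcvr.harmonize(_random_panel(rng), rescale=False)
        rescaled = wcvr.rescale_to_reference(h, ReferenceProportions.default())
        spec = wcvr.short_long_spec()
        assert not np.allclose(
            wcvr.compute_ratio(spec, rescaled).scores,
            wcvr.compute_ratio(spec, h).scores,
        )

    def test_invalid_reference_rejected(self):
        with pytest.raises(HarmonizationError):
            ReferenceProportions({p: 0.25 for p in PEPTIDES[:4]})
        with pytest.raises(HarmonizationError):
            ReferenceProportions(dict(zip(PEPTIDES, [0.3, 0.3, 0.3, 0.3, 0.3])))


def test_order_of_normalize_and_control_scale_preserves_ratios():
    """Total-normalization and control scaling commute at the ratio-score
    level when controls are profile-proportional: downstream biomarkers see
    identical values either way."""
    cfg = wcvr.SimulationConfig(n_cohorts=1, n_controls=4, n_cases=8,
                                n_replicates=1, noise_cv=0.0, seed=10)
    panel = wcvr.average_replicates(wcvr.generate_cohorts(cfg))
    a = wcvr.scale_by_control_means(wcvr.normalize_to_total(panel))
    b = wcvr.normalize_to_total(
        wcvr.PeptidePanel(wcvr.scale_by_control_means(panel).data)
    )
    spec = wcvr.short_long_spec()
    np.testing.assert_allclose(
        spec.evaluate(a.values), spec.evaluate(b.values), rtol=1e-12
    )


def test_full_pipeline_counts_zero_filtered(default_panel):
    h = wcvr.harmonize(default_panel)
    assert h.n_zero_filtered == 0
    assert h.reference_proportions is not None
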