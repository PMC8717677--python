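from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from drugspectrum import (
    CohortConfig,
    NormalizedCohort,
    assess_asymmetry,
    classify_attribute,
    classify_cohort,
    detect_breakpoint,
    generate_cohort,
    label_cohort,
    normalize_cohort,
    supports_importance,
)
from drugspectrum.classify import ClassificationParams, average_difference, render_classification_table

from test_simulate import two_block_specs


def brute_force_ks_edge(succ_counts, unsucc_counts, edges):
    """Independent oracle: exact-arithmetic exhaustive search over interior
    bin edges for the maximal |F_s - F_u|; returns (edges, max_gap) where
    ``edges`` is every argmax edge."""
    ns, nu = sum(succ_counts), sum(unsucc_counts)
    best_gap = Fraction(-1)
    best_edges = []
    for k in range(len(succ_counts) - 1):  # interior edges only
        fs = Fraction(sum(succ_counts[: k + 1]), ns)
        fu = Fraction(sum(unsucc_counts[: k + 1]), nu)
        gap = abs(fs - fu)
        if gap > best_gap:
            best_gap, best_edges = gap, [edges[k + 1]]
        elif gap == best_gap:
            best_edges.append(edges[k + 1])
    return best_edges, best_gap


class TestAssessAsymmetry:
    def test_zero_delta_is_symmetric(self):
        stat, asym = assess_asymmetry(np.zeros(10))
        assert stat == 0.0 and not asym

    def test_disjoint_distributions_reach_maximum(self):
        delta = np.array([1.0, 0.0, -1.0])
        stat, asym = assess_asymmetry(delta)
        assert stat == 1.0 and asym

    def test_half_sum_of_absolute_delta(self):
        delta = np.array([0.3, 0.0, -0.3, 0.0])
        stat, _ = assess_asymmetry(delta)
        assert stat == pytest.approx(0.3)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=20)
        d -= d.mean()
        assert assess_asymmetry(d)[0] == pytest.approx(assess_asymmetry(-d)[0])


class TestDetectBreakpoint:
    def test_disjoint_uniform_blocks(self):
        # successful mass uniform on [0, 0.5), unsuccessful on [0.5, 1]
        edges = np.linspace(0, 1, 11)
        succ = np.array([0.2] * 5 + [0.0] * 5)
        unsucc = np.array([0.0] * 5 + [0.2] * 5)
        has_bp, bp, purity = detect_breakpoint(succ, unsucc, edges)
        assert has_bp and bp == 0.5 and purity == 1.0

    def test_identical_rows_have_no_breakpoint(self):
        edges = np.linspace(0, 1, 6)
        row = np.array([0.2] * 5)
        has_bp, bp, purity = detect_breakpoint(row, row, edges)
        assert not has_bp and bp is None

    def test_interleaved_rows_have_low_purity(self):
        # alternating dominance, equal mass: asymmetric but no clean split
        edges = np.linspace(0, 1, 11)
        succ = np.array([0.2, 0.0] * 5)
        unsucc = np.array([0.0, 0.2] * 5)
        has_bp, bp, purity = detect_breakpoint(succ, unsucc, edges)
        assert purity < 0.75
        assert not has_bp and bp is None

    def test_degenerate_single_bin_rows(self):
        edges = np.linspace(0, 1, 6)
        row = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        has_bp, bp, purity = detect_breakpoint(row, row, edges)
        assert not has_bp and bp is None

    def test_tie_broken_toward_smallest_edge(self):
        # gaps are exact binary fractions so the tie is genuine in floats
        edges = np.linspace(0, 1, 5)
        succ = np.array([0.5, 0.0, 0.5, 0.0])
        unsucc = np.array([0.0, 0.5, 0.0, 0.5])
        _, _, _ = detect_breakpoint(succ, unsucc, edges)
        gaps = np.abs(np.cumsum(succ) - np.cumsum(unsucc))[:-1]
        assert gaps[0] == gaps[2]  # confirmed tie
        has_bp, bp, purity = detect_breakpoint(succ, unsucc, edges, purity_threshold=0.6)
        assert bp == edges[1]

    def test_matches_exhaustive_search_on_random_grids(self):
        """The KS-style argmax equals brute-force search over all interior
        edges, on random small two-group histograms."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(100):
            n_bins = int(rng.integers(2, 11))
            edges = np.linspace(0, 1, n_bins + 1)
            succ_c = rng.integers(0, 20, n_bins)
            unsucc_c = rng.integers(0, 20, n_bins)
            if succ_c.sum() == 0 or unsucc_c.sum() == 0:
                continue
            succ = succ_c / succ_c.sum()
            unsucc = unsucc_c / unsucc_c.sum()
            oracle_edges, oracle_gap = brute_force_ks_edge(
                succ_c.tolist(), unsucc_c.tolist(), edges
            )
            # force the candidate out regardless of thresholds
            has_bp, bp, _ = detect_breakpoint(
                succ, unsucc, edges, purity_threshold=1e-9, tau=1e-9
            )
            if oracle_gap == 0:
                assert not has_bp
                continue
            if len(oracle_edges) == 1:
                assert bp == pytest.approx(oracle_edges[0], abs=1e-12)
            else:
                assert any(bp == pytest.approx(e, abs=1e-12) for e in oracle_edges)
            checked += 1
        assert checked >= 80


class TestAverageDifference:
    def _cohort(self, succ_vals, unsucc_vals):
        vals = list(succ_vals) + list(unsucc_vals)
        labels = ["successful"] * len(succ_vals) + ["unsuccessful"] * len(unsucc_vals)
        index = pd.Index([f"P{i}" for i in range(len(vals))], name="patient_id")
        return NormalizedCohort(
            pd.DataFrame({"X": vals}, index=index),
            pd.Series(labels, index=index),
        )

    def test_identical_groups_zero_difference(self):
        nc = self._cohort([0.2, 0.4], [0.2, 0.4])
        assert average_difference(nc).loc["X", "mean_difference"] == 0.0

    def test_sign_flips_under_group_swap(self):
        nc = self._cohort([0.2, 0.4], [0.6, 0.8])
        d = average_difference(nc).loc["X", "mean_difference"]
        swapped = NormalizedCohort(
            nc.values,
            nc.labels.map({"successful": "unsuccessful", "unsuccessful": "successful"}),
        )
        assert average_difference(swapped).loc["X", "mean_difference"] == pytest.approx(-d)

    def test_empty_group_rejected(self):
        nc = self._cohort([0.2], [])
        with pytest.raises(ValueError, match="non-empty"):
            average_difference(nc)


class TestSupportsImportance:
    @pytest.mark.parametrize(
        "diff, expected",
        [(-0.0707, True), (0.0008, False), (0.05, False), (-0.05, False), (0.0501, True)],
    )
    def test_strict_absolute_threshold(self, diff, expected):
        assert supports_importance(diff) is expected


class TestClassify:
    def test_disjoint_blocks_are_important(self):
        edges = np.linspace(0, 1, 11)
        succ = np.array([0.2] * 5 + [0.0] * 5)
        unsucc = np.array([0.0] * 5 + [0.2] * 5)
        r = classify_attribute("X", succ, unsucc, edges, 0.25, 0.75)
        assert r.important and r.asymmetric and r.has_breakpoint
        assert r.breakpoint == 0.5
        assert r.mean_difference == pytest.approx(-0.5)

    def test_identical_rows_not_important(self):
        edges = np.linspace(0, 1, 11)
        row = np.full(10, 0.1)
        r = classify_attribute("X", row, row, edges, 0.5, 0.5)
        assert not r.important and not r.asymmetric and r.breakpoint is None

    def test_binary_attribute_flagged_degenerate(self):
        edges = np.linspace(0, 1, 11)
        succ = np.array([0.9] + [0.0] * 8 + [0.1])
        unsucc = np.array([0.1] + [0.0] * 8 + [0.9])
        r = classify_attribute("Sex", succ, unsucc, edges, 0.1, 0.9)
        assert r.has_breakpoint and r.degenerate_breakpoint

    def test_shifted_attributes_recovered_from_simulation(self):
        """Exactly the attributes generated with a dominance crossover are
        flagged important; null attributes are not."""
        shifted = ["HCT", "Cr", "Age"]
        specs = []
        for spec in two_block_specs(0.4, names=shifted):
            if spec.attribute_name not in shifted:
                # make every other attribute identically distributed
                spec = type(spec)(
                    attribute_name=spec.attribute_name,
                    distribution_family="truncated_normal",
                    successful_params=spec.successful_params,
                    unsuccessful_params=spec.successful_params,
                )
            specs.append(spec)
        config = CohortConfig(n_patients=2000, attribute_specs=tuple(specs), seed=21)
        nc = normalize_cohort(label_cohort(generate_cohort(config)))
        results, report = classify_cohort(nc)
        important = {r.attribute_name for r in results if r.important}
        assert important == set(shifted)
        assert report["params"] == {
            "n_bins": 50, "tau": 0.10, "purity_threshold": 0.75,
            "mean_diff_threshold": 0.05,
        }

    def test_deterministic_given_fixed_cohort(self, normalized):
        r1, rep1 = classify_cohort(normalized)
        r2, rep2 = classify_cohort(normalized)
        assert rep1 == rep2 and r1 == r2

    def test_rendered_table_lists_every_attribute(self, normalized):
        results, _ = classify_cohort(normalized)
        text = render_classification_table(results)
        for r in results:
            assert r.attribute_name in text

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClassificationParams(tau=0.0)
        with pytest.raises(ValueError):
            ClassificationParams(n_bins=1)
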