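import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from semmorph import categorize_effect, cliffs_delta, percent_change, summarize_groups
from semmorph.stats import cliffs_delta_bruteforce, violin_figure

samples = st.lists(st.integers(min_value=-20, max_value=20), min_size=1, max_size=40)


class TestCliffsDelta:
    def test_complete_separation(self):
        eff = cliffs_delta([1, 2, 3], [4, 5, 6])
        assert eff.delta == -1.0 and eff.category == "large" and eff.direction == -1

    def test_identical_samples_are_null(self):
        eff = cliffs_delta([3, 1, 4, 1, 5], [3, 1, 4, 1, 5])
        assert eff.delta == 0.0 and eff.category == "ns"

    def test_enumerated_four_pairs_with_tie(self):
        # pairs of ({1,2}, {1,3}): one tie, one x>y, two x<y -> (1-2)/4
        eff = cliffs_delta([1, 2], [1, 3])
        assert eff.delta == pytest.approx(-0.25)
        assert eff.category == "small"

    def test_empty_sample_is_hard_error(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(samples, samples)
    def test_equals_bruteforce_including_ties(self, x, y):
        assert cliffs_delta(x, y).delta == pytest.approx(
            cliffs_delta_bruteforce(x, y), abs=1e-12
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(samples, samples)
    def test_antisymmetry(self, x, y):
        assert cliffs_delta(x, y).delta == pytest.approx(-cliffs_delta(y, x).delta)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(samples, samples)
    def test_invariant_under_strictly_increasing_transform(self, x, y):
        f = lambda v: np.exp(np.asarray(v, dtype=float) / 10.0)
        assert cliffs_delta(x, y).delta == pytest.approx(
            cliffs_delta(f(x), f(y)).delta
        )


class TestCategorize:
    @pytest.mark.parametrize(
        "delta, category",
        [
            (0.0, "ns"), (0.146, "ns"), (0.147, "small"), (0.329, "small"),
            (0.33, "medium"), (0.473, "medium"), (0.474, "large"), (1.0, "large"),
            (-0.5, "large"), (-0.2, "small"),
        ],
    )
    def test_inclusive_thresholds(self, delta, category):
        assert categorize_effect(delta) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_effect(1.2)


class TestPercentChange:
    def test_examples(self):
        assert percent_change(0.5153, 0.3703) == 39.2
        assert percent_change(0.4645, 0.3703) == 25.4
        assert percent_change(1.0, 1.0) == 0.0

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)


def cell_table(rng, spec):
    """spec: {group: (n, area_mean, texture_mean)} -> tidy cell table."""
    frames = []
    for group, (n, area_mu, tex_mu) in spec.items():
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "area_um2": rng.lognormal(np.log(area_mu) - 0.045, 0.3, n),
                    "texture_value": rng.normal(tex_mu, 0.2 * tex_mu, n),
                    "texture_valid": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestSummarizeGroups:
    def test_null_case_identical_distributions(self):
        rng = np.random.default_rng(0)
        cells = cell_table(rng, {"ctrl": (500, 0.37, 0.021), "trt": (500, 0.37, 0.021)})
        groups, comps = summarize_groups(cells, control="ctrl")
        row = comps.set_index("group").loc["trt"]
        assert abs(row["area_um2_delta"]) < 0.05
        assert abs(row["area_um2_pct_change"]) < 5

    def test_known_area_shift_recovered(self):
        rng = np.random.default_rng(1)
        cells = cell_table(
            rng, {"ctrl": (1000, 0.40, 0.021), "trt": (1000, 0.50, 0.021)}
        )
        comps = summarize_groups(cells, control="ctrl")[1].set_index("group")
        assert comps.loc["trt", "area_um2_pct_change"] == pytest.approx(25, abs=5)
        assert comps.loc["trt", "area_um2_delta"] > 0.147

    def test_bookkeeping_counts_and_control_row(self):
        rng = np.random.default_rng(2)
        cells = cell_table(rng, {"ctrl": (120, 0.4, 0.02), "trt": (80, 0.4, 0.02)})
        groups, comps = summarize_groups(cells, control="ctrl")
        assert groups.set_index("group")["n_cells"].to_dict() == {"ctrl": 120, "trt": 80}
        ctrl = comps.set_index("group").loc["ctrl"]
        assert ctrl["area_um2_pct_change"] == 0.0 and ctrl["area_um2_delta"] == 0.0
        # quartiles ordered, sd non-negative
        g = groups.set_index("group").loc["trt"]
        assert g["area_um2_q1"] <= g["area_um2_median"] <= g["area_um2_q3"]
        assert g["area_um2_sd"] >= 0

    def test_texture_summary_respects_validity_flag(self):
        rng = np.random.default_rng(3)
        cells = cell_table(rng, {"ctrl": (50, 0.4, 0.02), "trt": (50, 0.4, 0.03)})
        cells.loc[cells.index[:10], "texture_valid"] = False
        groups, _ = summarize_groups(cells, control="ctrl")
        assert groups.set_index("group").loc["ctrl", "n_texture_value"] == 40

    def test_missing_control_is_hard_error(self):
        rng = np.random.default_rng(4)
        cells = cell_table(rng, {"a": (10, 0.4, 0.02)})
        with pytest.raises(ValueError, match="control"):
            summarize_groups(cells, control="zzz")

    def test_category_consistent_with_delta(self):
        rng = np.random.default_rng(5)
        cells = cell_table(
            rng, {"ctrl": (300, 0.4, 0.02), "t1": (300, 0.45, 0.022),
                  "t2": (300, 0.6, 0.03)}
        )
        _, comps = summarize_groups(cells, control="ctrl")
        for _, row in comps.iterrows():
            for metric in ("area_um2", "texture_value"):
                assert row[f"{metric}_category"] == categorize_effect(
                    row[f"{metric}_delta"]
                )

    def test_violin_export_writes_figure(self, tmp_path):
        rng = np.random.default_rng(6)
        cells = cell_table(rng, {"ctrl": (30, 0.4, 0.02), "trt": (30, 0.5, 0.03)})
        out = tmp_path / "violin.png"
        violin_figure(cells, "area_um2", out)
        assert out.exists() and out.stat().st_size > 0
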