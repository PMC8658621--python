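import numpy as np
import pandas as pd
import pytest

from ustiff.massmetrics import MassRecord
from ustiff.stats import (
    chi_squared,
    compare_mass_groups,
    comparisons_frame,
    mass_group_distributions,
    percentile_interval_5_95,
    records_frame,
    render_reports,
    welch_t_test,
)


def _record(histology, idx, hom=0.8, size="small", filtered=False):
    comps = {
        "soft_fat": 0.0, "intermediate_fat": 0.0, "hard_fat": 0.0,
        "soft_fibroglandular": 0.0, "intermediate_fibroglandular": 40.0,
        "hard_fibroglandular": 60.0,
    }
    return MassRecord(
        breast_id="b", histology=histology, stiffness_index=idx,
        pct_soft=0.0, pct_intermediate=40.0, pct_hard=60.0,
        component_pcts=comps, homogeneity=hom, equivalent_diameter_cm=1.0,
        size_class=size, filtered=filtered,
    )


class TestWelch:
    def test_closed_form_example(self):
        t, df, p = welch_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_identical_groups_give_t0_p1(self):
        t, _, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_p_invariant_under_group_swap(self, rng):
        xs, ys = rng.normal(0, 1, 9), rng.normal(0.4, 2, 7)
        t1, df1, p1 = welch_t_test(xs, ys)
        t2, df2, p2 = welch_t_test(ys, xs)
        assert p1 == pytest.approx(p2)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])


class TestChiSquared:
    def test_closed_form_example(self):
        chi2, df, p = chi_squared([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20.0 / 3.0, abs=1e-9)
        assert df == 1

    def test_proportional_rows_give_zero(self):
        chi2, _, p = chi_squared([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_to_permutations(self, rng):
        table = rng.integers(1, 30, (3, 4))
        base = chi_squared(table)[0]
        assert chi_squared(table[::-1])[0] == pytest.approx(base)
        assert chi_squared(table[:, ::-1])[0] == pytest.approx(base)
        assert chi_squared(table.T)[0] == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared([[0, 0], [5, 5]])


class TestPercentileInterval:
    def test_known_range(self):
        assert percentile_interval_5_95(np.arange(101)) == (5.0, 95.0)

    def test_constant_sample(self):
        assert percentile_interval_5_95([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        xs = rng.normal(0, 1, 37)
        v = np.sort(xs)
        n = len(v)

        def quantile(q):
            h = q * (n - 1)
            lo = int(np.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, n - 1)] - v[lo])

        lo, hi = percentile_interval_5_95(xs)
        assert lo == pytest.approx(quantile(0.05))
        assert hi == pytest.approx(quantile(0.95))


class TestCompareMassGroups:
    def test_row_count_is_pairs_times_metrics_per_stratum(self, rng):
        records = []
        for hist, mu in [("cancer", 0.8), ("fibroadenoma", 0.5), ("cyst", 0.2)]:
            for _ in range(5):
                records.append(_record(hist, float(np.clip(mu + rng.normal(0, 0.05), 0, 1))))
        comps = compare_mass_groups(records)
        assert len(comps) == 3 * 2  # one stratum, 3 pairs, 2 metrics
        frame = comparisons_frame(comps)
        assert set(frame.metric) == {"stiffness_index", "homogeneity"}

    def test_small_groups_skipped(self, rng):
        records = [_record("cancer", 0.8), _record("cancer", 0.75)]
        records += [_record("cyst", 0.2), _record("cyst", 0.25)]
        records += [_record("fibroadenoma", 0.5)]  # n=1: skipped
        comps = compare_mass_groups(records, metrics=("stiffness_index",))
        pairs = {(c.group_a, c.group_b) for c in comps}
        assert pairs == {("cancer", "cyst")}

    def test_separated_groups_detected(self, rng):
        records = [_record("cancer", float(v)) for v in rng.normal(0.8, 0.03, 20)]
        records += [_record("cyst", float(v)) for v in rng.normal(0.2, 0.03, 20)]
        comps = compare_mass_groups(records, metrics=("stiffness_index",))
        assert comps[0].t_p < 0.05 and comps[0].significant

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            compare_mass_groups([])


def test_report_bundle_round_trips(tmp_path, rng):
    records = []
    for hist, mu in [("cancer", 0.8), ("fibroadenoma", 0.5), ("cyst", 0.2)]:
        for _ in range(4):
            records.append(_record(hist, float(np.clip(mu + rng.normal(0, 0.05), 0, 1))))
    comps = compare_mass_groups(records)
    from ustiff.volumetrics import COMPONENT_ORDER, table_from_volumes

    volumes = table_from_volumes({c: 100.0 for c in COMPONENT_ORDER})
    written = render_reports(volumes, records, comps, tmp_path)
    assert set(written) == {
        "component_volumes", "mass_records", "mass_group_distributions",
        "group_comparisons",
    }
    vol_back = pd.read_csv(written["component_volumes"], index_col=0)
    pd.testing.assert_frame_equal(vol_back, volumes, check_exact=False)
    recs_back = pd.read_csv(written["mass_records"])
    assert len(recs_back) == len(records)
    np.testing.assert_allclose(
        recs_back["stiffness_index"], records_frame(records)["stiffness_index"]
    )
    dist = pd.read_csv(written["mass_group_distributions"])
    comp_cols = [c for c in dist.columns if c.startswith("pct_")]
    np.testing.assert_allclose(dist[comp_cols].sum(axis=1), 100.0)


def test_empty_mass_list_yields_volumes_only(tmp_path):
    from ustiff.volumetrics import COMPONENT_ORDER, table_from_volumes

    volumes = table_from_volumes({c: 50.0 for c in COMPONENT_ORDER})
    written = render_reports(volumes, [], [], tmp_path)
    assert set(written) == {"component_volumes"}
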