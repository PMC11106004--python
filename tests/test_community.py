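"""Rarefaction filtering, normalization, summaries, quadrants, persistence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from picoseason.community import (
    CommunityParams,
    apply_detection_limit,
    classify_persistence,
    filter_samples,
    normalize,
    quadrant_assign,
    rarefaction_slope,
    summarize,
)


def mc_endpoint_slope(counts, reps=10000, seed=0):
    """Monte-Carlo oracle: richness drop when one read is removed.

    Resamples n = N-1 reads without replacement and estimates
    E[S(N)] - E[S(N-1)] directly from the definition.
    """
    rng = np.random.default_rng(seed)
    reads = np.repeat(np.arange(len(counts)), counts)
    s_full = len(counts)
    drops = np.empty(reps)
    for i in range(reps):
        sub = rng.choice(reads, size=len(reads) - 1, replace=False)
        drops[i] = s_full - len(np.unique(sub))
    return drops.mean(), drops.std(ddof=1) / np.sqrt(reps)


class TestRarefactionSlope:
    def test_all_distinct_reads_slope_one(self):
        assert rarefaction_slope([1] * 1000) == pytest.approx(1.0)

    def test_single_dominant_asv_slope_zero(self):
        assert rarefaction_slope([1000]) == pytest.approx(0.0)

    def test_singleton_fraction_closed_form(self):
        counts = [1] * 50 + [950]
        assert rarefaction_slope(counts) == pytest.approx(50 / 1000)

    def test_matches_monte_carlo_subsampling_oracle(self):
        counts = [1] * 12 + [3, 7, 40, 200]
        slope = rarefaction_slope(counts)
        mc, se = mc_endpoint_slope(counts, reps=10000, seed=1)
        assert abs(slope - mc) <= 3 * se

    def test_too_few_reads_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_slope([1])


def _tax(rows):
    return pd.DataFrame(rows, columns=["asv_id", "marker", "category", "group",
                                       "genus", "species"])


TAX = _tax([
    ("a_pras1", "plastid16S", "plastid", "prasinophyte-CII", "Ostreococcus", ""),
    ("a_pras2", "plastid16S", "plastid", "prasinophyte-CVI", "Prasinoderma", ""),
    ("a_prym", "plastid16S", "plastid", "prymnesiophyte", "", ""),
    ("a_cyano", "plastid16S", "cyanobacteria", "cyanobacteria-Pro", "", ""),
    ("a_het", "plastid16S", "heterotroph", "heterotroph-bacteria", "", ""),
])


def _table(records):
    return pd.DataFrame(records, columns=["sample_id", "asv_id", "count"])


class TestFilterSamples:
    def test_saturated_sample_kept(self):
        t = _table([("s1", "a_het", 9995)] + [(f"s1", f"a_pras{i%2+1}", 1) for i in range(5)])
        t = t.groupby(["sample_id", "asv_id"], as_index=False)["count"].sum()
        rep = filter_samples(t, TAX)
        assert rep.loc[0, "kept"]
        assert rep.loc[0, "slope"] < 0.001

    def test_unsaturated_sample_rejected(self):
        t = _table([("s1", f"a{i}", 1) for i in range(20)])
        tax = _tax([(f"a{i}", "plastid16S", "heterotroph", "h", "", "") for i in range(20)])
        rep = filter_samples(t, tax)
        assert not rep.loc[0, "kept"]
        assert "slope" in rep.loc[0, "reason"]

    def test_low_plastid_sample_flagged_not_dropped(self):
        t = _table([("s1", "a_het", 10000), ("s1", "a_pras1", 30)])
        rep = filter_samples(t, TAX)
        assert rep.loc[0, "kept"] and rep.loc[0, "low_plastid"]


class TestNormalize:
    def test_plastid_denominator_fraction(self):
        t = _table([("s1", "a_pras1", 40), ("s1", "a_prym", 60), ("s1", "a_het", 900)])
        rel = normalize(t, TAX, denominator="plastid", unit="group")
        v = rel.set_index("unit")["value"]
        assert v["prasinophyte-CII"] == pytest.approx(0.40)
        assert v["prymnesiophyte"] == pytest.approx(0.60)

    def test_group_fractions_sum_to_one(self):
        t = _table([("s1", "a_pras1", 13), ("s1", "a_pras2", 7), ("s1", "a_prym", 29)])
        rel = normalize(t, TAX, denominator="plastid", unit="group")
        assert rel["value"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_denominator_sample_absent(self):
        t = _table([("s1", "a_het", 500)])
        rel = normalize(t, TAX, denominator="plastid", unit="group")
        assert rel.empty

    def test_unknown_denominator_rejected(self):
        with pytest.raises(ValueError):
            normalize(_table([("s1", "a_het", 5)]), TAX, denominator="archaea")

    @given(st.integers(2, 50))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        t = _table([("s1", "a_pras1", 11), ("s1", "a_prym", 31), ("s1", "a_pras2", 3)])
        t2 = t.assign(count=t["count"] * k)
        r1 = normalize(t, TAX, "plastid", "asv").set_index("unit")["value"]
        r2 = normalize(t2, TAX, "plastid", "asv").set_index("unit")["value"]
        assert np.allclose(r1.sort_index(), r2.sort_index())


class TestSummarize:
    def _meta(self):
        return pd.DataFrame({
            "sample_id": ["s1", "s2", "s3"],
            "period": ["DM", "DM", "SS"],
            "zone": ["ml", "ml", "surface"],
        })

    def test_two_sample_mean_and_sd(self):
        rel = pd.DataFrame({"sample_id": ["s1", "s2"], "unit": ["g", "g"],
                            "value": [0.2, 0.4]})
        out = summarize(rel, self._meta())
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["sd"] == pytest.approx(0.141421356, abs=1e-6)
        assert row["n"] == 2

    def test_single_sample_group_has_no_sd(self):
        rel = pd.DataFrame({"sample_id": ["s3"], "unit": ["g"], "value": [0.7]})
        out = summarize(rel, self._meta())
        assert np.isnan(out.iloc[0]["sd"]) and out.iloc[0]["n"] == 1


def sort_percentile(values, q):
    """Independent order-statistic oracle with linear interpolation."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestQuadrants:
    def test_assignment_with_known_thresholds(self):
        # thresholds land at the published style values by construction
        chla = pd.Series([0.10, 0.12, 0.15, 0.188, 0.25], index=list("abcde"))
        pras = pd.Series([0.10, 0.20, 0.30, 0.332, 0.40], index=list("abcde"))
        depth = pd.Series([10.0] * 5, index=list("abcde"))
        df, chla_thr, pras_thr = quadrant_assign(chla, pras, depth)
        assert chla_thr == pytest.approx(sort_percentile(chla, 0.75))
        assert df.loc["e", "quadrant"] == "Q4"   # both strictly above
        assert df.loc["a", "quadrant"] == "Q1"   # both below
        assert df.loc["d", "quadrant"] == "Q1"   # exactly at both thresholds

    def test_thresholds_match_sort_oracle_and_partition(self):
        rng = np.random.default_rng(12)
        n = 120
        idx = [f"s{i}" for i in range(n)]
        chla = pd.Series(rng.lognormal(-2, 0.7, n), index=idx)
        pras = pd.Series(rng.beta(2, 4, n), index=idx)
        depth = pd.Series(rng.uniform(1, 300, n), index=idx)
        df, ct, pt = quadrant_assign(chla, pras, depth)
        elig = depth[depth <= 140.0]
        assert ct == pytest.approx(sort_percentile(chla[elig.index], 0.75), abs=1e-12)
        assert pt == pytest.approx(sort_percentile(pras[elig.index], 0.75), abs=1e-12)
        assert len(df) == len(elig)
        assert df["quadrant"].isin(["Q1", "Q2", "Q3", "Q4"]).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(40)]
        chla = pd.Series(rng.lognormal(-2, 0.5, 40), index=idx)
        pras = pd.Series(rng.beta(2, 3, 40), index=idx)
        depth = pd.Series(rng.uniform(1, 100, 40), index=idx)
        _, c1, p1 = quadrant_assign(chla, pras, depth)
        perm = rng.permutation(idx)
        _, c2, p2 = quadrant_assign(chla[perm], pras[perm], depth[perm])
        assert (c1, p1) == (c2, p2)

    def test_too_few_samples_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        d = pd.Series([5.0, 5.0], index=["a", "b"])
        with pytest.raises(ValueError):
            quadrant_assign(s, s, d)


def _persist_inputs():
    meta = pd.DataFrame({
        "sample_id": ["m1", "m2", "m3", "m4", "m5", "deep", "old"],
        "period": ["DM", "ST", "SS", "AT", "DM", "SS", "DM"],
        "depth_m": [10, 10, 10, 10, 10, 200, 10],
        "timestamp": ["2017-02-01", "2018-04-15", "2018-07-01", "2019-10-20",
                      "2019-01-10", "2018-07-01", "2016-02-01"],
    })
    table = pd.DataFrame([
        # detected in DM only, three years
        ("m1", "dm_only", 5), ("m5", "dm_only", 2), ("old", "dm_only", 9),
        # all four periods
        ("m1", "everywhere", 3), ("m2", "everywhere", 4),
        ("m3", "everywhere", 1), ("m4", "everywhere", 2),
        # exactly one read in the restricted window
        ("m3", "single", 1),
        # detections only outside the restriction (deep + excluded year)
        ("deep", "deep_only", 50), ("old", "old_only", 50),
    ], columns=["sample_id", "asv_id", "count"])
    return table, meta


class TestPersistence:
    def test_categories_and_restrictions(self):
        table, meta = _persist_inputs()
        records, sets = classify_persistence(table, meta)
        by_id = {r.asv_id: r for r in records}
        assert by_id["dm_only"].category == "ephemeral"
        assert by_id["dm_only"].periods == frozenset({"DM"})
        assert by_id["dm_only"].n_years == 2  # 2016 detection excluded
        assert by_id["everywhere"].category == "persistent"
        assert "single" not in by_id          # singleton excluded
        assert "deep_only" not in by_id       # below the depth cut
        assert "old_only" not in by_id        # outside analysis years
        assert sets["period_sets"]["DM"] == {"dm_only", "everywhere"}

    def test_two_period_asv_is_intermediate(self):
        table, meta = _persist_inputs()
        table = pd.concat([table, pd.DataFrame(
            [("m1", "two", 2), ("m3", "two", 2)],
            columns=["sample_id", "asv_id", "count"])])
        records, _ = classify_persistence(table, meta)
        rec = {r.asv_id: r for r in records}["two"]
        assert rec.category == "intermediate"
        assert rec.n_periods_detected == 2

    def test_ss_only_year_overlap_sets(self):
        table, meta = _persist_inputs()
        table = pd.concat([table, pd.DataFrame(
            [("m3", "summer", 4)], columns=["sample_id", "asv_id", "count"])])
        _, sets = classify_persistence(table, meta)
        assert sets["ss_only_by_year"][2018] == {"summer"}


class TestDetectionLimit:
    @pytest.mark.parametrize("value,lod,expected", [
        (0.04, 0.05, 0.0),
        (0.05, 0.05, 0.05),   # boundary value kept
        (0.2, 0.03, 0.2),
    ])
    def test_examples(self, value, lod, expected):
        assert apply_detection_limit([value], lod)[0] == expected

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            apply_detection_limit([-0.1], 0.05)
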