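"""Replicate combination, WT/G31C index, hit calling, internal controls."""

import numpy as np
import pandas as pd
import pytest

import riboscreen as rs
from riboscreen.screen import HIGH_FLUOR, LOW_FLUOR

from conftest import run_fast_screen


def rep_table(values_by_strain, rep="rep1"):
    rows = [(s, v) for s, vals in values_by_strain.items() for v in vals]
    df = pd.DataFrame(rows, columns=["strain_id", "ratio_corrected"])
    df["replicate_id"] = rep
    return df


def strain_table(values_by_strain):
    return pd.DataFrame(
        {"strain_id": list(values_by_strain),
         "mean": list(values_by_strain.values()),
         "sd": 0.0, "n": 3}
    )


class TestCombineReplicates:
    def test_mean_and_sd(self):
        tables = [rep_table({"a": [v]}) for v in (1.0, 1.1, 0.9)]
        out = rs.combine_replicates(tables)
        assert out.loc[0, "mean"] == pytest.approx(1.0)
        assert out.loc[0, "sd"] == pytest.approx(0.1)
        assert out.loc[0, "n"] == 3

    def test_duplicates_averaged_within_replicate_first(self):
        t1 = rep_table({"a": [1.2, 1.4]})
        t2 = rep_table({"a": [1.0]}, rep="rep2")
        out = rs.combine_replicates([t1, t2])
        assert out.loc[0, "mean"] == pytest.approx((1.3 + 1.0) / 2)

    def test_single_replicate_warns_sd_missing(self):
        with pytest.warns(UserWarning, match="replicates"):
            out = rs.combine_replicates([rep_table({"a": [1.0]})])
        assert np.isnan(out.loc[0, "sd"])

    def test_sd_tracks_planted_cv(self):
        """3 replicates at 10% CV: median per-strain SD ~ 0.1 x mean."""
        rng = np.random.default_rng(0)
        sigma = np.sqrt(np.log1p(0.1**2))
        strains = [f"s{i}" for i in range(2000)]
        tables = [
            rep_table({s: [float(rng.lognormal(-sigma**2 / 2, sigma))]
                       for s in strains}, rep=f"rep{r}")
            for r in range(3)
        ]
        out = rs.combine_replicates(tables)
        ratio = (out["sd"] / out["mean"]).median()
        assert ratio == pytest.approx(0.1, rel=0.25)


class TestControlNormalize:
    def test_identical_screens_give_unit_index(self):
        wt = strain_table({"a": 1.2, "b": 0.8, "c": 1.0})
        out = rs.control_normalize(wt, wt.copy())
        assert np.allclose(out["index"], 1.0)

    def test_missing_strains_reported_not_dropped(self):
        wt = strain_table({"a": 1.0, "b": 2.0})
        ctrl = strain_table({"a": 1.0, "c": 1.0})
        out = rs.control_normalize(wt, ctrl).set_index("strain_id")
        assert np.isnan(out.loc["b", "index"])
        assert out.loc["b", "reason"] == "MISSING_CTRL"
        assert out.loc["c", "reason"] == "MISSING_WT"

    def test_planted_effects(self):
        """A 3x WT-only strain indexes at ~3; a 3x both-reporter artifact
        indexes at ~1."""
        strains = {f"s{i}": 1.0 for i in range(50)}
        wt = dict(strains, hit=3.0, artifact=3.0)
        ctrl = dict(strains, hit=1.0, artifact=3.0)
        out = rs.control_normalize(strain_table(wt),
                                   strain_table(ctrl)).set_index("strain_id")
        assert out.loc["hit", "index"] == pytest.approx(3.0, rel=1e-6)
        assert out.loc["artifact", "index"] == pytest.approx(1.0, rel=1e-6)


class TestCallHits:
    def make_index(self, values):
        return pd.DataFrame({"strain_id": [f"s{i}" for i in range(len(values))],
                             "index": values})

    def test_planted_hit_called_high(self):
        rng = np.random.default_rng(0)
        vals = list(1 + 0.05 * rng.standard_normal(500)) + [2.0]
        hits = rs.call_hits(self.make_index(vals), 5.0)
        assert "s500" in set(hits["strain_id"])
        assert (hits.set_index("strain_id").loc["s500", "direction"]
                == HIGH_FLUOR)
        assert (hits.set_index("strain_id").loc["s500", "tpp_call"]
                == "LOW_TPP")

    def test_tight_null_produces_no_hits(self):
        rng = np.random.default_rng(1)
        hits = rs.call_hits(
            self.make_index(1 + 0.02 * rng.standard_normal(3800)), 5.0)
        assert len(hits) == 0

    def test_threshold_monotonic(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([1 + 0.05 * rng.standard_normal(1000),
                               [1.3, 1.5, 2.0, 0.6, 0.4]])
        h5 = set(rs.call_hits(self.make_index(vals), 5.0)["strain_id"])
        h6 = set(rs.call_hits(self.make_index(vals), 6.0)["strain_id"])
        assert h6 <= h5

    def test_tie_at_threshold_included(self):
        """Strains sitting exactly on the +/- 5 SD bands are hits
        (>= / <= rule)."""
        base = [0.9] * 50 + [1.1] * 50
        # MAD is insensitive to the two extreme points, so the scale can be
        # computed beforehand with extreme placeholders and the edge strains
        # planted exactly on the resulting thresholds
        probe = np.log(np.array(base + [0.1, 10.0]))
        sd = 1.4826 * np.median(np.abs(probe - np.median(probe)))
        df = self.make_index(base + [np.exp(5 * sd), np.exp(-5 * sd)])
        hits = rs.call_hits(df, 5.0).set_index("strain_id")
        assert hits.loc["s100", "direction"] == HIGH_FLUOR
        assert hits.loc["s101", "direction"] == LOW_FLUOR
        lo, hi = hits.attrs["bands"]
        assert lo == np.exp(-5 * sd) and hi == np.exp(5 * sd)

    def test_too_few_indices_error(self):
        with pytest.raises(ValueError, match="defined"):
            rs.call_hits(self.make_index([1.0] * 5), 5.0)

    def test_degenerate_distribution_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            rs.call_hits(self.make_index([1.0] * 100), 5.0)

    def test_null_false_positive_rate(self):
        """3800 null indices at SD 0.02: mean hits/screen << 1 (Gaussian
        tail 2*Phi(-5)*3800 ~ 0.002)."""
        total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            total += len(rs.call_hits(
                self.make_index(1 + 0.02 * rng.standard_normal(3800)), 5.0))
        assert total / 50 < 0.05


class TestDuplicateConcordance:
    def test_identical_pair_zero_log2(self, spec):
        pmap = rs.generate_plate_map(spec, 100, 10,
                                     n_empty=spec.density - 110, seed=0)
        dup = pmap[pmap["strain_id"] != rs.EMPTY]["strain_id"].value_counts()
        t = pmap.copy()
        t["replicate_id"] = "rep1"
        t["ratio_corrected"] = 1.7
        pairs, summary = rs.duplicate_concordance([t], pmap)
        assert len(pairs) == (dup == 2).sum() == 10
        assert np.allclose(pairs["log2_diff"], 0.0)
        assert summary["frac_within_1_5_fold"] == 1.0

    def test_no_duplicates_warns_empty(self, spec):
        pmap = rs.generate_plate_map(spec, 50, 0,
                                     n_empty=spec.density - 50, seed=0)
        t = pmap.copy()
        t["ratio_corrected"] = 1.0
        with pytest.warns(UserWarning, match="duplicated"):
            pairs, summary = rs.duplicate_concordance([t], pmap)
        assert summary["n_pairs"] == 0

    def test_402_pairs_and_monte_carlo_dispersion(self):
        """Full screen: 402 pairs per replicate; median |log2 difference|
        matches a Monte-Carlo oracle of two mean-1 lognormals at the same CV."""
        bundle = run_fast_screen(0)
        pairs, summary = rs.duplicate_concordance(
            bundle["normalized"]["WT"], bundle["map"])
        assert summary["n_pairs"] == 3 * 402
        rng = np.random.default_rng(123)
        sigma = np.sqrt(np.log1p(0.1**2))
        a, b = rng.lognormal(0, sigma, (2, 200_000))
        oracle = np.median(np.abs(np.log2(a / b)))
        assert summary["median_abs_log2"] == pytest.approx(oracle, rel=0.15)


class TestReplicatePearson:
    def test_self_correlation_is_one(self):
        t = strain_table({f"s{i}": 1 + 0.1 * i for i in range(20)})
        m = rs.replicate_pearson([t, t.copy()])
        assert m.iloc[0, 1] == pytest.approx(1.0)

    def test_pure_noise_uncorrelated(self):
        rng = np.random.default_rng(0)
        mk = lambda: strain_table(
            {f"s{i}": v for i, v in enumerate(1 + 0.1 * rng.standard_normal(1000))})
        m = rs.replicate_pearson([mk(), mk()])
        assert abs(m.iloc[0, 1]) < 0.1

    def test_signal_dominant_replicates_correlate(self):
        """Shared biological variance >> replicate noise gives r > 0.9."""
        rng = np.random.default_rng(1)
        signal = 1 + 0.4 * rng.standard_normal(1000)
        mk = lambda: strain_table(
            {f"s{i}": s + 0.1 * rng.standard_normal()
             for i, s in enumerate(signal)})
        m = rs.replicate_pearson([mk(), mk()])
        assert m.iloc[0, 1] > 0.9

    def test_too_few_shared_strains(self):
        a = strain_table({"a": 1.0, "b": 2.0})
        b = strain_table({"a": 1.0, "c": 2.0})
        with pytest.raises(ValueError, match="shared"):
            rs.replicate_pearson([a, b])


class TestRenderOutputs:
    def test_empty_hit_set_writes_valid_csvs(self, tmp_path):
        idx = pd.DataFrame({"strain_id": ["a", "b"], "index": [1.0, np.nan]})
        hits = pd.DataFrame(
            columns=["strain_id", "index", "sd_distance", "direction"])
        written = rs.render_outputs(idx, hits, None, tmp_path)
        high = pd.read_csv(written["hits_high.csv"])
        assert list(high.columns) and len(high) == 0
        unscored = pd.read_csv(written["unscored.csv"])
        assert "b" in set(unscored["strain_id"])

    def test_heatmap_matrix_shape(self, tmp_path, spec):
        bundle = run_fast_screen(1, n_strains=1400, n_duplicates=0, n_plates=1)
        rec = bundle["normalized"]["WT"][0]
        written = rs.render_outputs(bundle["index"], bundle["hits"], rec,
                                    tmp_path)
        mat = np.loadtxt(written["heatmap_plate1.csv"], delimiter=",")
        assert mat.shape == (32, 48)

    def test_top_high_hit_is_largest_planted_effect(self):
        bundle = run_fast_screen(2, n_strains=1400, n_duplicates=0, n_plates=1,
                                 truth_kwargs={"n_high": 5, "n_low": 1,
                                               "n_artifact": 2})
        top_planted = max(
            (s for s, v in bundle["truth"].riboswitch_effect.items() if v > 1),
            key=lambda s: bundle["truth"].riboswitch_effect[s])
        high = bundle["hits"][bundle["hits"]["direction"] == HIGH_FLUOR]
        assert high.iloc[0]["strain_id"] == top_planted
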