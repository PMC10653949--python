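import numpy as np
import pandas as pd
import pytest

from magdyn.dynamics import (
    CwmTrajectories,
    community_weighted_means,
    detect_shifts,
    filter_prevalent,
    treatment_intervals,
)
from magdyn.io import AbundanceTable


def rel_table(rows, cols, index=None):
    df = pd.DataFrame(rows, columns=cols, index=index, dtype=float)
    return AbundanceTable(df.div(df.sum(axis=1), axis=0), "relative")


def design(n_ind, treatments=("T1", "T2"), species="sp"):
    rows = []
    for i in range(n_ind):
        for t, tr in enumerate(treatments, start=1):
            rows.append(
                {
                    "sample_id": f"i{i}_t{t}",
                    "individual_id": f"i{i}",
                    "cage_id": f"c{i % 2}",
                    "species": species,
                    "treatment": tr,
                    "time_index": t,
                }
            )
    return pd.DataFrame(rows)


class TestPrevalenceFilter:
    def test_column_max_rule(self):
        rows = [
            [0.9979, 0.002, 0.0001, 0.00005, 0.00005] ,
            [0.999, 0.0002, 0.0004, 0.0002, 0.0002],
        ]
        abund = rel_table(rows, list("abcde"))
        out = filter_prevalent(abund, 0.001)
        assert list(out.df.columns) == ["a", "b"]  # hand scan of column maxima
        assert np.allclose(out.df.sum(axis=1), 1.0)

    def test_boundary_exactly_at_threshold_kept(self):
        rows = [[0.999, 0.001]]
        out = filter_prevalent(rel_table(rows, ["a", "b"]), 0.001)
        assert "b" in out.df.columns

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.full(30, 0.2), size=8)
        abund = AbundanceTable(pd.DataFrame(rows, columns=[f"m{i}" for i in range(30)]), "relative")
        once = filter_prevalent(abund, 0.001)
        twice = filter_prevalent(once, 0.001)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_all_removed_is_error(self):
        abund = rel_table([[0.5, 0.5]], ["a", "b"])
        with pytest.raises(ValueError, match="every MAG"):
            filter_prevalent(abund, 0.9)


class TestCwm:
    def test_examples(self):
        mci = pd.DataFrame({"f": [0.2, 0.8]}, index=["a", "b"])
        cwm = community_weighted_means(rel_table([[0.5, 0.5]], ["a", "b"]), mci)
        assert cwm.iloc[0, 0] == pytest.approx(0.5)
        mci2 = pd.DataFrame({"f": [0.1, 0.9]}, index=["a", "b"])
        cwm2 = community_weighted_means(rel_table([[0.9, 0.1]], ["a", "b"]), mci2)
        assert cwm2.iloc[0, 0] == pytest.approx(0.18)

    def test_all_capacity_one_gives_one(self):
        mci = pd.DataFrame({"f": [1.0, 1.0, 1.0]}, index=list("abc"))
        cwm = community_weighted_means(rel_table([[0.2, 0.5, 0.3]], list("abc")), mci)
        assert cwm.iloc[0, 0] == pytest.approx(1.0)

    def test_bounded_by_present_mcis(self):
        rng = np.random.default_rng(1)
        mci = pd.DataFrame(rng.uniform(size=(6, 3)), index=[f"m{i}" for i in range(6)])
        p = rng.dirichlet(np.ones(6))
        abund = AbundanceTable(
            pd.DataFrame([p], columns=mci.index), "relative"
        )
        cwm = community_weighted_means(abund, mci).iloc[0]
        assert (cwm >= mci.min()).all() and (cwm <= mci.max()).all()

    def test_missing_mci_row_keyed(self):
        mci = pd.DataFrame({"f": [0.2]}, index=["a"])
        with pytest.raises(KeyError, match="b"):
            community_weighted_means(rel_table([[0.5, 0.5]], ["a", "b"]), mci)

    def test_duplicating_a_mag_and_splitting_abundance_is_invariant(self):
        mci = pd.DataFrame({"f": [0.3, 0.7]}, index=["a", "b"])
        base = community_weighted_means(rel_table([[0.6, 0.4]], ["a", "b"]), mci)
        mci_dup = pd.DataFrame({"f": [0.3, 0.3, 0.7]}, index=["a1", "a2", "b"])
        split = community_weighted_means(
            rel_table([[0.3, 0.3, 0.4]], ["a1", "a2", "b"]), mci_dup
        )
        assert split.iloc[0, 0] == pytest.approx(base.iloc[0, 0])


class TestIntervals:
    def _cwm(self, values, meta):
        return pd.DataFrame({"f1": values}, index=meta["sample_id"])

    def test_identical_samples_zero_width(self):
        meta = design(4)
        cwm = self._cwm([0.42] * len(meta), meta)
        res = treatment_intervals(cwm, meta, n_boot=200, seed=0)
        assert np.allclose(res.table["interval_low"], 0.42)
        assert np.allclose(res.table["interval_high"], 0.42)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        meta = design(8)
        cwm = self._cwm(rng.uniform(0.2, 0.8, len(meta)), meta)
        res = treatment_intervals(cwm, meta, n_boot=300, seed=1)
        t = res.table
        assert ((t["interval_low"] <= t["cwm_mean"]) & (t["cwm_mean"] <= t["interval_high"])).all()

    def test_disjoint_supports_do_not_overlap_and_flag(self):
        meta = design(5)
        values = [0.1 if r["treatment"] == "T1" else 0.8 for _, r in meta.iterrows()]
        rng = np.random.default_rng(3)
        values = np.array(values) + rng.normal(0, 0.01, len(values))
        res = treatment_intervals(self._cwm(values, meta), meta, n_boot=300, seed=2)
        shifts = detect_shifts(res)
        assert shifts["shift"].all()
        assert (shifts["direction"] == 1).all()

    def test_width_shrinks_with_more_individuals(self):
        def width(n_ind, seed):
            rng = np.random.default_rng(seed)
            meta = design(n_ind, treatments=("T1",))
            cwm = self._cwm(rng.uniform(0.3, 0.7, len(meta)), meta)
            t = treatment_intervals(cwm, meta, n_boot=400, seed=0).table
            return float((t["interval_high"] - t["interval_low"]).iloc[0])

        assert width(20, 4) < width(5, 4)

    def test_single_individual_treatment_flagged_undefined(self):
        meta = design(1)
        cwm = self._cwm([0.5, 0.6], meta)
        with pytest.warns(UserWarning, match="interval undefined"):
            res = treatment_intervals(cwm, meta, n_boot=50, seed=0)
        assert not res.table["defined"].any()

    def test_cage_level_resampling_option(self):
        rng = np.random.default_rng(6)
        meta = design(8)
        cwm = self._cwm(rng.uniform(0.2, 0.8, len(meta)), meta)
        res = CwmTrajectories(cwm, meta, resample_unit="cage_id").fit(
            n_boot=200, seed=0
        )
        t = res.table
        assert ((t["interval_low"] <= t["cwm_mean"]) & (t["cwm_mean"] <= t["interval_high"])).all()
        with pytest.raises(ValueError, match="no 'litter'"):
            CwmTrajectories(cwm, meta, resample_unit="litter")

    def test_treatment_order_follows_time_index(self):
        meta = design(3, treatments=("Later", "Earlier")[::-1])
        cwm = self._cwm([0.5] * len(meta), meta)
        model = CwmTrajectories(cwm, meta)
        assert model.treatment_order == ["Earlier", "Later"]


class TestShiftDetection:
    def _traj(self, rows, order):
        from magdyn.dynamics import TrajectoryResults

        table = pd.DataFrame(
            rows,
            columns=["function_id", "treatment", "cwm_mean", "interval_low",
                     "interval_high", "n_samples", "defined"],
        )
        return TrajectoryResults(table=table, level=0.9, n_boot=100, treatment_order=order)

    def test_overlapping_intervals_not_flagged(self):
        res = self._traj(
            [["f", "A", 0.5, 0.4, 0.6, 5, True], ["f", "B", 0.55, 0.45, 0.65, 5, True]],
            ["A", "B"],
        )
        out = detect_shifts(res)
        assert not out["shift"].iloc[0]

    def test_disjoint_intervals_flagged_with_direction(self):
        res = self._traj(
            [["f", "A", 0.15, 0.1, 0.2, 5, True], ["f", "B", 0.35, 0.3, 0.4, 5, True]],
            ["A", "B"],
        )
        out = detect_shifts(res)
        assert out["shift"].iloc[0] and out["direction"].iloc[0] == 1

    def test_undefined_interval_skipped_with_warning(self):
        res = self._traj(
            [["f", "A", 0.15, 0.1, 0.2, 5, True], ["f", "B", 0.35, np.nan, np.nan, 1, False]],
            ["A", "B"],
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = detect_shifts(res)
        assert out.empty
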