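import numpy as np
import pandas as pd
import pytest

from toxmod import SyntheticConfig, generate_study
from toxmod.errors import ComputationError
from toxmod.preprocess import (filter_probes, condition_log_ratios,
                               collapse_probes, select_disease_conditions,
                               qc_replicate_clustering)


def _toy_tables(toy_samples, values):
    cols = list(toy_samples.index)
    intensity = pd.DataFrame(values, columns=cols)
    intensity.index = pd.Index([f"p{i:02d}" for i in range(len(values))],
                               name="probe_id")
    presence = pd.DataFrame(1, index=intensity.index, columns=cols)
    return intensity, presence


class TestFilterProbes:
    def test_rule_by_rule_on_toy_table(self, toy_samples):
        """Hand-built 10-probe table: survivors match a manual application of
        the three rules (annotation, IQR quantile, present calls)."""
        rng = np.random.default_rng(0)
        base = rng.normal(8, 0.01, size=(10, 8))
        # probes 0..4 get large spread across conditions, 5..9 almost none
        for i in range(5):
            base[i] += np.array([3, 3, -3, -3, 0, 0, 1, -1]) * (i + 1)
        intensity, presence = _toy_tables(toy_samples, base)
        ann = pd.Series({f"p{i:02d}": f"g{i}" for i in range(10)})
        ann["p03"] = ""                      # unannotated
        presence.loc["p04"] = 0              # never present
        kept, report = filter_probes(intensity, presence, toy_samples, ann,
                                     iqr_quantile=0.5, present_frac=0.25)
        # manual: p03 out (annotation), p04 out (presence);
        # IQR median over the 9 annotated probes keeps the high-spread ones
        assert "p03" not in kept.index
        assert "p04" not in kept.index
        assert {"p00", "p01", "p02"} <= set(kept.index)
        assert report.n_removed_unannotated == 1
        assert report.n_removed_absent >= 1
        assert report.n_kept == len(kept)

    def test_constant_probe_removed(self, toy_samples):
        rng = np.random.default_rng(1)
        vals = rng.normal(8, 1, size=(6, 8))
        vals[5] = 7.0                        # exactly constant -> IQR 0
        intensity, presence = _toy_tables(toy_samples, vals)
        ann = pd.Series({p: f"g{i}" for i, p in enumerate(intensity.index)})
        kept, _ = filter_probes(intensity, presence, toy_samples, ann)
        assert "p05" not in kept.index

    def test_idempotent(self, toy_samples):
        rng = np.random.default_rng(2)
        intensity, presence = _toy_tables(
            toy_samples, rng.normal(8, 1, size=(12, 8)))
        ann = pd.Series({p: f"g{i}" for i, p in enumerate(intensity.index)})
        once, _ = filter_probes(intensity, presence, toy_samples, ann,
                                iqr_quantile=0.3)
        twice, _ = filter_probes(once, presence.loc[once.index], toy_samples,
                                 ann, iqr_quantile=0.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_removed_raises(self, toy_samples):
        intensity, presence = _toy_tables(toy_samples, np.full((3, 8), 5.0))
        ann = pd.Series({p: "" for p in intensity.index})
        with pytest.raises(ComputationError):
            filter_probes(intensity, presence, toy_samples, ann)


class TestConditionLogRatios:
    def test_mean_arithmetic(self, toy_samples):
        intensity, _ = _toy_tables(toy_samples, np.zeros((1, 8)))
        intensity.loc["p00", ["condA_t0", "condA_t1"]] = [4.0, 6.0]
        intensity.loc["p00", ["condA_c0", "condA_c1"]] = [3.0, 5.0]
        lr = condition_log_ratios(intensity, toy_samples)
        assert lr.at["p00", "condA"] == pytest.approx(1.0)

    def test_treated_equal_control_gives_zero(self, toy_samples):
        rng = np.random.default_rng(3)
        vals = rng.normal(8, 1, size=(4, 8))
        intensity, _ = _toy_tables(toy_samples, vals)
        intensity[["condB_t0", "condB_t1"]] = \
            intensity[["condB_c0", "condB_c1"]].values
        lr = condition_log_ratios(intensity, toy_samples)
        assert np.allclose(lr["condB"].values, 0.0)

    def test_uneven_replicates_match_spreadsheet(self):
        """3 conditions with unequal replicate counts: spreadsheet-style
        recomputation (explicit means) matches."""
        rows = []
        vals = {}
        rng = np.random.default_rng(4)
        for cid, n_t, n_c in (("c1", 3, 2), ("c2", 2, 4), ("c3", 1, 1)):
            for r in range(n_t):
                sid = f"{cid}_t{r}"
                rows.append((sid, cid, "x", 1.0, 1.0, "treated", f"ctl_{cid}", 0))
                vals[sid] = rng.normal(8, 1)
            for r in range(n_c):
                sid = f"{cid}_c{r}"
                rows.append((sid, f"ctl_{cid}", "x", 0.0, 1.0, "control", "", 0))
                vals[sid] = rng.normal(8, 1)
        samples = pd.DataFrame(
            rows, columns=["sample_id", "condition_id", "chemical", "dose",
                           "duration", "group", "control_condition_id",
                           "histopath_score"]).set_index("sample_id")
        intensity = pd.DataFrame([vals], index=pd.Index(["p00"], name="probe_id"))
        lr = condition_log_ratios(intensity, samples)
        for cid, n_t, n_c in (("c1", 3, 2), ("c2", 2, 4), ("c3", 1, 1)):
            t_mean = np.mean([vals[f"{cid}_t{r}"] for r in range(n_t)])
            c_mean = np.mean([vals[f"{cid}_c{r}"] for r in range(n_c)])
            assert lr.at["p00", cid] == pytest.approx(t_mean - c_mean)

    def test_missing_control_names_condition(self, toy_samples):
        samples = toy_samples.copy()
        samples.loc[samples["condition_id"] == "condB",
                    "control_condition_id"] = "nonexistent"
        intensity, _ = _toy_tables(samples, np.zeros((1, 8)))
        with pytest.raises(ComputationError, match="condB"):
            condition_log_ratios(intensity, samples)

    def test_linearity_in_treated_intensity(self, toy_samples):
        rng = np.random.default_rng(5)
        intensity, _ = _toy_tables(toy_samples, rng.normal(8, 1, size=(5, 8)))
        lr0 = condition_log_ratios(intensity, toy_samples)
        shifted = intensity.copy()
        shifted[["condA_t0", "condA_t1"]] += 0.75
        lr1 = condition_log_ratios(shifted, toy_samples)
        assert np.allclose(lr1["condA"] - lr0["condA"], 0.75)
        assert np.allclose(lr1["condB"], lr0["condB"])


class TestCollapseProbes:
    def test_one_probe_per_gene_is_relabeling(self):
        m = pd.DataFrame(np.arange(12.0).reshape(3, 4),
                         index=["p1", "p2", "p3"])
        out = collapse_probes(m, pd.Series({"p1": "gA", "p2": "gB", "p3": "gC"}))
        assert list(out.index) == ["gA", "gB", "gC"]
        assert np.array_equal(out.values, m.values)

    def test_higher_iqr_probe_wins(self):
        m = pd.DataFrame([[0, 1, 2, 10], [0, 1, 2, 3]], index=["p1", "p2"],
                         dtype=float)
        out = collapse_probes(m, pd.Series({"p1": "g", "p2": "g"}))
        assert list(out.index) == ["g"]
        assert np.array_equal(out.values[0], [0, 1, 2, 10])

    def test_iqr_tie_breaks_lexicographically(self):
        m = pd.DataFrame([[0.0, 1.0], [5.0, 6.0]], index=["pB", "pA"])
        out = collapse_probes(m, pd.Series({"pB": "g", "pA": "g"}))
        assert np.array_equal(out.values[0], [5.0, 6.0])   # pA's row


class TestDiseaseConditionSelection:
    def _samples(self, scores):
        rows = []
        for cid, score in scores.items():
            rows.append((f"{cid}_t0", cid, "x", 1.0, 1.0, "treated",
                         f"ctl_{cid}", score))
            rows.append((f"{cid}_c0", f"ctl_{cid}", "x", 0.0, 1.0,
                         "control", "", score))
        return pd.DataFrame(
            rows, columns=["sample_id", "condition_id", "chemical", "dose",
                           "duration", "group", "control_condition_id",
                           "histopath_score"]).set_index("sample_id")

    def test_severity_above_one_selected(self):
        """Four fibrosis-grade conditions (score 2) among sub-threshold rows
        are exactly the selected set."""
        scores = {"anit30_7d": 2, "anit60_7d": 2, "mda81_5d": 2,
                  "ndma10_5d": 2, "croto750_5d": 1, "benign_3d": 0,
                  "mild_1d": 1}
        sel = select_disease_conditions(self._samples(scores))
        assert sel == ["anit30_7d", "anit60_7d", "mda81_5d", "ndma10_5d"]

    def test_all_below_threshold_empty(self):
        assert select_disease_conditions(
            self._samples({"a": 1, "b": 0})) == []

    def test_threshold_zero_strict(self):
        sel = select_disease_conditions(
            self._samples({"a": 0, "b": 1, "c": 2}), score_threshold=0)
        assert sel == ["b", "c"]


class TestReplicateQC:
    def _study(self, null_condition: bool, seed: int):
        cfg = SyntheticConfig(
            n_genes=500, n_conditions=20, n_planted_deg=60, n_coexpr_blocks=2,
            block_size=20, network_nodes=100, planted_module_size=10,
            n_absent_genes=0, n_unannotated_probes=0, n_duplicate_probes=0,
            include_null_disease_condition=null_condition, seed=seed)
        return generate_study(cfg)

    def test_unshifted_condition_fails_qc(self):
        study = self._study(True, 1)
        cand = select_disease_conditions(study.samples)
        report = qc_replicate_clustering(study.intensity, study.samples, cand)
        null_cond = study.truth.null_disease_condition
        assert null_cond in report.index
        assert not report.loc[null_cond, "qc_pass"]

    def test_shifted_conditions_pass_qc(self):
        study = self._study(False, 2)
        cand = select_disease_conditions(study.samples)
        report = qc_replicate_clustering(study.intensity, study.samples, cand)
        assert report["qc_pass"].all()

    def test_null_condition_flag_rate_across_seeds(self):
        """A zero-shift condition labelled diseased is caught by the
        replicate-clustering QC in at least 95% of generator seeds."""
        flagged = 0
        n_seeds = 100
        for seed in range(n_seeds):
            study = self._study(True, 1000 + seed)
            cand = select_disease_conditions(study.samples)
            report = qc_replicate_clustering(study.intensity, study.samples,
                                             cand)
            if not report.loc[study.truth.null_disease_condition, "qc_pass"]:
                flagged += 1
        assert flagged >= 0.95 * n_seeds

    def test_too_few_candidates_raise(self, toy_samples):
        intensity = pd.DataFrame(np.zeros((2, 8)),
                                 columns=list(toy_samples.index))
        with pytest.raises(ComputationError):
            qc_replicate_clustering(intensity, toy_samples, ["condA"])
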