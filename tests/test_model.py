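import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline

import oracles
from seqsol.features import FEATURE_NAMES, feature_table, feature_vector
from seqsol.model import (
    FeatureStats,
    SequenceFeaturizer,
    TailContrastRegressor,
    eliminate_features,
    fit,
    load_model,
    predict,
    save_model,
    scale_feature,
)
from seqsol.seqio import ProteinSequence, TrainingRecord
from seqsol.synthetic import SyntheticSpec, generate, make_tm_decoy


def _frame_from_rows(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES), dtype=float)


def _single_feature_frame(n: int, feature: str, rng) -> tuple[pd.DataFrame, np.ndarray]:
    """A feature frame where only one column varies, linearly with y."""
    y = np.linspace(10.0, 90.0, n)
    rows = []
    for yi in y:
        row = {f: 0.5 for f in FEATURE_NAMES}
        row[feature] = yi / 100.0
        rows.append(row)
    return _frame_from_rows(rows), y


class TestFit:
    def test_single_separating_feature_takes_all_weight(self, rng):
        X, y = _single_feature_frame(100, "KmR", rng)
        m = TailContrastRegressor(select_features=False).fit(X, y)
        assert m.stats_.loc["KmR", "weight"] == pytest.approx(1.0)
        assert (m.stats_.drop("KmR")["weight"] == 0.0).all()

    def test_degenerate_feature_carries_no_weight(self):
        recs = generate(SyntheticSpec(n=60, length_range=(80, 80)), 0)
        m = fit(recs, tail_fraction=0.2)
        # all sequences share one length, so the length feature is constant
        assert m.stats_.loc["length", "pooled_sd"] == 0.0
        assert m.stats_.loc["length", "z"] == 0.0
        assert m.stats_.loc["length", "weight"] == 0.0

    def test_weights_sum_to_one_on_any_fit(self):
        for seed in range(3):
            recs = generate(SyntheticSpec(n=80), seed)
            m = fit(recs, tail_fraction=0.15)
            assert m.stats_.loc[m.active_, "weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_midpopulation_duplicate_leaves_tails_unchanged(self):
        # n chosen so the ceiling tail size (9) survives adding one record
        recs = generate(SyntheticSpec(n=85), 1)
        m1 = fit(recs, tail_fraction=0.1)
        median_rec = sorted(recs, key=lambda r: r.solubility)[42]
        extra = TrainingRecord("dup", median_rec.sequence, median_rec.solubility)
        m2 = fit(recs + [extra], tail_fraction=0.1)
        pd.testing.assert_frame_equal(
            m1.stats_[["mean_low", "mean_high"]], m2.stats_[["mean_low", "mean_high"]]
        )

    def test_too_few_records_rejected(self):
        recs = generate(SyntheticSpec(n=50), 0)[:30]
        with pytest.raises(ValueError, match="40"):
            fit(recs)

    def test_constant_solubility_rejected(self):
        recs = [TrainingRecord(r.id, r.sequence, 50.0)
                for r in generate(SyntheticSpec(n=50), 0)]
        with pytest.raises(ValueError, match="equal"):
            fit(recs)

    def test_tm_records_excluded_from_training(self):
        recs = generate(SyntheticSpec(n=100, length_range=(60, 120)), 3)
        decoys = [TrainingRecord(f"tm{i}", make_tm_decoy(recs[i].sequence, i), recs[i].solubility)
                  for i in range(10)]
        m_clean = fit(recs, tail_fraction=0.1)
        m_mixed = fit(recs + decoys, tail_fraction=0.1)
        pd.testing.assert_frame_equal(m_clean.stats_, m_mixed.stats_)


class TestScaleFeature:
    STATS = FeatureStats("f", mean_low=2.0, mean_high=6.0, pooled_sd=1.0, z=4.0, weight=0.5)

    def test_anchors_and_midpoint(self):
        assert scale_feature(2.0, self.STATS) == 0.0
        assert scale_feature(6.0, self.STATS) == 1.0
        assert scale_feature(4.0, self.STATS) == 0.5

    def test_clamping(self):
        assert scale_feature(100.0, self.STATS) == 1.0
        assert scale_feature(-100.0, self.STATS) == 0.0

    def test_lowering_feature_reverses_direction(self):
        rev = FeatureStats("f", mean_low=6.0, mean_high=2.0, pooled_sd=1.0, z=-4.0, weight=0.5)
        assert scale_feature(6.0, rev) == 0.0
        assert scale_feature(2.0, rev) == 1.0

    def test_degenerate_stats_give_half(self):
        flat = FeatureStats("f", mean_low=3.0, mean_high=3.0, pooled_sd=0.0, z=0.0, weight=0.0)
        assert scale_feature(99.0, flat) == 0.5


class TestPredict:
    def test_tail_mean_anchors_predict_zero_and_one(self):
        """Inputs at the low/high tail means score exactly 0 and 1."""
        m = TailContrastRegressor(select_features=False).fit(
            *_single_feature_frame(100, "hydropathy", None)
        )
        low = m.stats_["mean_low"]
        high = m.stats_["mean_high"]
        X = pd.DataFrame([low.to_dict(), high.to_dict()], columns=list(FEATURE_NAMES))
        assert m.predict(X)[0] == 0.0
        assert m.predict(X)[1] == 1.0

    def test_scaled_in_unit_interval_for_arbitrary_sequences(self, random_sequences):
        recs = generate(SyntheticSpec(n=100), 0)
        m = fit(recs, tail_fraction=0.1)
        scaled = m.predict(random_sequences)
        assert np.all(scaled >= 0.0) and np.all(scaled <= 1.0)

    def test_percent_is_affine_in_scaled(self):
        recs = generate(SyntheticSpec(n=100), 2)
        m = fit(recs, tail_fraction=0.1)
        seqs = [r.sequence for r in recs[:10]]
        scaled, percent = m.predict(seqs), m.predict_percent(seqs)
        assert np.allclose(percent, m.percent_low_ + scaled * (m.percent_high_ - m.percent_low_))
        assert m.percent_high_ > m.percent_low_

    def test_prediction_result_diagnostics(self):
        recs = generate(SyntheticSpec(n=100, length_range=(60, 120)), 4)
        m = fit(recs, tail_fraction=0.1)
        seq = make_tm_decoy(recs[0].sequence, 0)
        res = predict(seq, m)
        assert res.tm_flag and 0.0 <= res.scaled <= 1.0
        assert set(res.deviations) == set(FEATURE_NAMES)
        fv = feature_vector(seq)
        expected = (fv["KmR"] - m.population_means_["KmR"]) / m.population_sds_["KmR"]
        assert res.deviations["KmR"] == pytest.approx(expected)


class TestElimination:
    def test_single_active_feature_returned_unchanged(self, rng):
        X, y = _single_feature_frame(100, "V", rng)
        m = TailContrastRegressor(select_features=False).fit(X, y)
        assert [f for f in m.active_ if m.stats_.loc[f, "weight"] > 0] == ["V"]
        before = m.stats_.copy()
        m._eliminate(X, y)
        assert m.stats_.loc["V", "weight"] == pytest.approx(1.0)
        pd.testing.assert_frame_equal(before[["z"]], m.stats_[["z"]])

    def test_elimination_keeps_or_improves_training_correlation(self):
        recs = generate(SyntheticSpec(n=300), 7)
        m_full = fit(recs, tail_fraction=0.1)
        seqs = [r.sequence for r in recs]
        y = np.array([r.solubility for r in recs])
        from seqsol.profiles import detect_tm
        keep = [not detect_tm(s).flag for s in seqs]
        frame = feature_table([s for s, k in zip(seqs, keep) if k])
        r_full = m_full._train_correlation(frame, y[keep])
        m_elim = eliminate_features(m_full, recs)
        assert m_elim.train_correlation_ >= r_full - m_full.elimination_tol

    def test_recovered_z_signs_match_generating_directions(self):
        inf = {"G": (1, 1.0), "I": (1, 1.0), "M": (-1, 1.0), "N": (1, 1.0), "T": (-1, 1.0)}
        recs = generate(SyntheticSpec(n=500, informative_features=inf), 11)
        m = fit(recs)
        for feature, (direction, _) in inf.items():
            assert np.sign(m.stats_.loc[feature, "z"]) == direction


class TestPersistence:
    def test_round_trip_is_lossless(self, tmp_path):
        recs = generate(SyntheticSpec(n=80), 5)
        m = eliminate_features(fit(recs, tail_fraction=0.1), recs)
        path = tmp_path / "m.psol"
        save_model(m, path)
        loaded = load_model(path)
        pd.testing.assert_frame_equal(m.stats_, loaded.stats_, atol=1e-12, rtol=0)
        assert loaded.active_ == m.active_
        assert loaded.percent_low_ == m.percent_low_
        assert loaded.percent_high_ == m.percent_high_
        assert loaded.population_mean_scaled_ == m.population_mean_scaled_
        assert np.allclose(loaded.population_means_, m.population_means_, atol=1e-12)
        seqs = [r.sequence for r in recs[:5]]
        assert np.array_equal(m.predict(seqs), loaded.predict(seqs))

    def test_truncated_file_rejected(self, tmp_path):
        recs = generate(SyntheticSpec(n=80), 5)
        m = fit(recs, tail_fraction=0.1)
        path = tmp_path / "m.psol"
        save_model(m, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:10]) + "\n")
        with pytest.raises(ValueError, match="truncated|incomplete"):
            load_model(path)

    def test_future_version_rejected_naming_versions(self, tmp_path):
        path = tmp_path / "m.psol"
        path.write_text("seqsol-model\t99\n")
        with pytest.raises(ValueError, match="99.*1|1.*99"):
            load_model(path)

    def test_foreign_file_rejected(self, tmp_path):
        path = tmp_path / "m.psol"
        path.write_text("something else\n")
        with pytest.raises(ValueError, match="not a"):
            load_model(path)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        m = TailContrastRegressor(tail_fraction=0.1, select_features=False)
        assert m.get_params()["tail_fraction"] == 0.1
        m2 = clone(m).set_params(tail_fraction=0.2)
        assert m2.get_params()["tail_fraction"] == 0.2

    def test_pipeline_with_featurizer(self):
        recs = generate(SyntheticSpec(n=80), 6)
        pipe = Pipeline([
            ("featurize", SequenceFeaturizer()),
            ("model", TailContrastRegressor(tail_fraction=0.1, select_features=False)),
        ])
        seqs = [r.sequence for r in recs]
        y = [r.solubility for r in recs]
        pipe.fit(seqs, y)
        pred = pipe.predict(seqs[:5])
        assert pred.shape == (5,) and np.all((0 <= pred) & (pred <= 1))

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="fit"):
            TailContrastRegressor().predict(["MKV"])
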