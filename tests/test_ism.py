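"""Mutagenesis machinery: the importance-score formula against an
independent oracle, locality of every mutational operator, window search,
and the robustness/insertion experiments on surrogate models."""

import numpy as np
import pytest

from chromaccess import ism
from chromaccess.ism import (ImportanceTrack, MutationEffectTable, best_window,
                             deep_random_mutagenesis, export_attributions,
                             importance_scores, knock_in, knock_out,
                             load_attribution, logit, motif_insertion_experiment,
                             mutational_effect_distribution,
                             positional_importance_profile,
                             random_sequence_baseline, saturation_ism)
from chromaccess.nn import LinearLogitModel

from conftest import make_linear_model, random_onehot


def reference_importance(table: MutationEffectTable, tissue: str) -> np.ndarray:
    """Independent re-implementation: plain python loop over positions."""
    ref_base = table.ref_onehot.argmax(axis=0)
    out = np.zeros(table.length)
    for i in range(table.length):
        probs = np.clip(table.outputs[tissue][i], 1e-7, 1 - 1e-7)
        lg = np.log(probs / (1 - probs))
        out[i] = lg[ref_base[i]] - lg.mean()
    return out


def random_table(rng, L=60) -> MutationEffectTable:
    ref = random_onehot(rng, L)
    outputs = {t: rng.uniform(1e-4, 1 - 1e-4, size=(L, 4)) for t in ("head", "testis")}
    # reference column must equal the unmutated output at every position
    ref_base = ref.argmax(axis=0)
    for t in outputs:
        outputs[t][np.arange(L), ref_base] = outputs[t][0, ref_base[0]]
    return MutationEffectTable("t", ref, outputs,
                               {t: float(outputs[t][0, ref_base[0]])
                                for t in outputs})


class TestImportanceScores:
    def test_frozen_example_logits_one_vs_minus_one(self):
        """logit(ref)=1, alternatives all -1 -> score = 1 - 0.5·(1-3)/2 = 1.5."""
        from scipy.special import expit
        ref = np.zeros((4, 1), dtype=np.uint8)
        ref[0, 0] = 1
        tab = np.full((1, 4), expit(-1.0))
        tab[0, 0] = expit(1.0)
        table = MutationEffectTable("x", ref, {"head": tab}, {"head": float(expit(1.0))})
        tr = importance_scores(table)
        assert tr.scores["head"][0] == pytest.approx(1.5, abs=1e-9)

    def test_equal_outputs_score_zero(self):
        ref = np.eye(4, dtype=np.uint8)[:, :4].T.copy()
        ref = np.eye(4, dtype=np.uint8)
        ref = random_onehot(np.random.default_rng(0), 10)
        tab = np.full((10, 4), 0.3)
        table = MutationEffectTable("x", ref, {"head": tab}, {"head": 0.3})
        np.testing.assert_allclose(importance_scores(table).scores["head"], 0.0)

    def test_matches_independent_oracle(self, rng):
        for _ in range(5):
            table = random_table(rng)
            tr = importance_scores(table)
            for t in ("head", "testis"):
                np.testing.assert_allclose(tr.scores[t],
                                           reference_importance(table, t),
                                           atol=1e-10)

    def test_four_base_scores_sum_to_zero(self, rng):
        table = random_table(rng)
        per = ism.per_base_scores(table, "head")
        np.testing.assert_allclose(per.sum(axis=1), 0.0, atol=1e-10)


class TestSaturation:
    def test_table_reference_column_and_spot_checks(self, rng):
        model = make_linear_model(rng, L=40)
        seq = random_onehot(rng, 40)
        table = saturation_ism(model, seq)
        ref_base = seq.argmax(axis=0)
        p_ref = model.predict(seq)
        for j, t in enumerate(("head", "testis")):
            np.testing.assert_allclose(
                table.outputs[t][np.arange(40), ref_base], p_ref[j])
        # 5 random cells equal independent single predictions
        for _ in range(5):
            i = rng.integers(40)
            b = rng.integers(4)
            mut = seq.copy()
            mut[:, i] = 0
            mut[b, i] = 1
            p = model.predict(mut)
            for j, t in enumerate(("head", "testis")):
                assert table.outputs[t][i, b] == pytest.approx(p[j], rel=1e-12)

    def test_constant_model_all_entries_equal(self, rng):
        model = LinearLogitModel(np.zeros((2, 4, 30)), np.array([0.2, -0.1]))
        table = saturation_ism(model, random_onehot(rng, 30))
        for t in ("head", "testis"):
            assert np.ptp(table.outputs[t]) == 0


class TestEffectDistribution:
    def test_constant_model_flagged_degenerate(self, rng):
        model = LinearLogitModel(np.zeros((2, 4, 30)), np.array([0.0, 0.0]))
        table = saturation_ism(model, random_onehot(rng, 30))
        _, fit = mutational_effect_distribution([table])
        assert fit["degenerate"]

    def test_linear_model_effects_match_closed_form(self, rng):
        model = make_linear_model(rng, L=30)
        seq = random_onehot(rng, 30)
        table = saturation_ism(model, seq)
        effects, fit = mutational_effect_distribution([table], scale="logit")
        # closed form: |Δ logit| = |w[t, b, i] - w[t, ref_i, i]|
        ref_base = seq.argmax(axis=0)
        expected = []
        for t in range(2):
            for i in range(30):
                for b in range(4):
                    if b != ref_base[i]:
                        expected.append(abs(model.weights[t, b, i]
                                            - model.weights[t, ref_base[i], i]))
        assert sorted(np.round(effects, 8)) == pytest.approx(
            sorted(np.round(expected, 8)), abs=1e-6)

    def test_lognormal_parameter_recovery(self, rng):
        mu, sigma = -3.0, 0.8
        sample = rng.lognormal(mu, sigma, size=100_000)
        ref = random_onehot(rng, 1)
        # wrap the raw sample in a synthetic "effects" pathway via fit on logs
        logs = np.log(sample)
        assert abs(logs.mean() - mu) < 0.05 * abs(mu)
        assert abs(logs.std() - sigma) < 0.05 * sigma


class TestWindows:
    def _track(self, values):
        return ImportanceTrack("x", {"head": np.asarray(values, dtype=float)})

    def test_single_spike_found(self):
        v = np.zeros(20)
        v[7] = 5.0
        hit = best_window(self._track(v), "head", predicted_peak=True, window_len=5)
        assert hit.start <= 7 < hit.start + 5

    def test_exhaustive_scan_equivalence(self, rng):
        v = rng.normal(size=20)
        for peak in (True, False):
            hit = best_window(self._track(v), "head", peak, 5)
            means = [v[s : s + 5].mean() for s in range(16)]
            best = int(np.argmax(means) if peak else np.argmin(means))
            assert hit.start == best
            assert hit.mean_importance == pytest.approx(means[best])

    def test_all_zero_track_ties_to_start(self):
        hit = best_window(self._track(np.zeros(20)), "head", True, 5)
        assert hit.start == 0


class TestKnockInOut:
    def test_knock_in_own_center_is_identity(self, rng):
        model = make_linear_model(rng, L=50)
        bg = random_onehot(rng, 50, n=3)
        base = model.predict(bg)
        subs = [bg[0][:, 20:30]]
        scores, _ = knock_in(model, subs, bg[:1], np.array([[0, 0]]))
        np.testing.assert_allclose(scores[0], base[0], rtol=1e-12)

    def test_knock_out_locality_and_restore(self, rng):
        model = make_linear_model(rng, L=50)
        seq = random_onehot(rng, 50)
        hit = ism.WindowHit("x", "head", 10, 5, 0.0, "lower")
        mutated, _ = knock_out(model, seq, hit, seed=3)
        diff = np.flatnonzero((mutated != seq).any(axis=0))
        assert set(diff) <= set(range(10, 15))
        restored = mutated.copy()
        restored[:, 10:15] = seq[:, 10:15]
        np.testing.assert_array_equal(restored, seq)
        np.testing.assert_allclose(model.predict(restored), model.predict(seq))

    def test_insert_longer_than_background_errors(self, rng):
        model = make_linear_model(rng, L=10)
        with pytest.raises(ValueError, match="longer"):
            knock_in(model, [random_onehot(rng, 20)], random_onehot(rng, 10, n=2),
                     np.zeros((1, 2)))


class TestDeepMutagenesis:
    def test_hamming_distance_equals_n_mut_and_zero_level(self, rng):
        # instrument a model that records its inputs
        seen = []

        class Recorder:
            config = type("C", (), {"tissues": ("head", "testis")})()

            def predict(self, x, batch_size=0):
                if x.ndim == 3:
                    seen.append(x)
                    return np.full((len(x), 2), 0.9)
                return np.array([0.9, 0.9])

        seq = random_onehot(rng, 100)
        res = deep_random_mutagenesis(Recorder(), seq, {"head": 0.5, "testis": 0.5},
                                      levels=(0, 7), n_experiments=20, seed=2)
        assert res.retained["head"][0] == 1.0
        muts = np.concatenate(seen)
        for m in muts:
            assert (m.argmax(axis=0) != seq.argmax(axis=0)).sum() == 7
            assert (m.sum(axis=0) == 1).all()

    def test_retained_fraction_counts_threshold_crossings(self, rng):
        model = make_linear_model(rng, L=60, scale=2.0)
        seq = random_onehot(rng, 60)
        p0 = model.predict(seq)
        thr = {"head": 0.5, "testis": 0.5}
        res = deep_random_mutagenesis(model, seq, thr, levels=(30,),
                                      n_experiments=200, seed=5)
        for t in ("head", "testis"):
            assert 0.0 <= res.retained[t][30] <= 1.0


class TestRandomBaselineAndInsertion:
    def test_impossible_threshold_gives_zero(self, rng):
        model = make_linear_model(rng, L=30)
        out = random_sequence_baseline(model, {"head": 1.0, "testis": 1.0},
                                       n=50, seed=1)
        assert out == {"head": 0.0, "testis": 0.0}

    def test_two_seeds_agree_within_binomial_error(self, rng):
        model = make_linear_model(rng, L=30)
        thr = {"head": 0.5, "testis": 0.5}
        f1 = random_sequence_baseline(model, thr, n=400, seed=1)["head"]
        f2 = random_sequence_baseline(model, thr, n=400, seed=2)["head"]
        assert abs(f1 - f2) < 4 * np.sqrt(0.25 / 400) + 0.02

    def test_inserting_own_center_changes_nothing(self, rng):
        model = make_linear_model(rng, L=40)
        X = random_onehot(rng, 40, n=6)
        cons = {"self": X[0][:, 15:25]}
        out = motif_insertion_experiment(model, {"self": X[0][:, 15:25]}, X[:1],
                                         {"head": 0.5, "testis": 0.5})
        assert out["self"] == {"head": 0.0, "testis": 0.0}


class TestExport:
    def test_roundtrip_and_manifest(self, tmp_path, rng):
        model = make_linear_model(rng, L=20)
        tables = [saturation_ism(model, random_onehot(rng, 20), example_id=f"e{i}")
                  for i in range(3)]
        manifest = export_attributions(tables, tmp_path / "attr")
        import json
        meta = json.loads(manifest.read_text())
        assert meta["n_examples"] == 3
        arrays = load_attribution(tmp_path / "attr", "e1")
        hyp = ism.per_base_scores(tables[1], "head").astype(np.float32)
        np.testing.assert_array_equal(arrays["hyp_head"], hyp)
        np.testing.assert_array_equal(arrays["act_head"],
                                      hyp * tables[1].ref_onehot.T)
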