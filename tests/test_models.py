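import numpy as np
import pandas as pd
import pytest

from autogs.models import (
    ENV_VARIABLES,
    EnvFeatureVector,
    ModelSpec,
    aggregate_env,
    build_model,
    encoding_for_model,
    read_env_csv,
)
from autogs.models.deep import DeepGSNet, DLGWASNet, DNNGPNet, SoyDNGPNet
from autogs.models.envse import EnvSENet
from autogs.models.nn import Conv1d, TrainConfig
from autogs.models.pool import MODEL_NAMES


@pytest.fixture(scope="module")
def additive_data():
    rng = np.random.default_rng(5)
    n, L = 64, 100
    x = rng.integers(0, 3, (n, L)).astype(float)
    beta = np.zeros(L)
    beta[rng.choice(L, 12, replace=False)] = rng.normal(0, 1, 12)
    y = x @ beta
    return x, y


def _encode_for(name, x):
    if encoding_for_model(name) == "dosage_vector":
        return x
    if name == "DLGWAS":
        out = np.zeros((x.shape[0], 4, x.shape[1]))
        for ch, v in enumerate((0, 1, 2)):
            out[:, ch, :] = x == v
        return out
    if name == "SoyDNGP":
        s = int(np.sqrt(x.shape[1]))
        out = np.zeros((x.shape[0], 3, s * s))
        for ch, v in enumerate((0, 1, 2)):
            out[:, ch, :] = x[:, : s * s] == v
        return out.reshape(x.shape[0], 3, s, s)
    if name == "DNNGP":
        xc = x - x.mean(axis=0)
        u, sv, vt = np.linalg.svd(xc, full_matrices=False)
        return xc @ vt[:50].T
    raise AssertionError(name)


class TestModelSpec:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError) as exc:
            ModelSpec(name="NotAModel")
        for name in MODEL_NAMES:
            assert name in str(exc.value)

    def test_incompatible_encoding_rejected(self):
        with pytest.raises(ValueError, match="requires encoding"):
            ModelSpec(name="DLGWAS", encoding="dosage_vector")

    def test_encoding_defaults(self):
        assert ModelSpec(name="RF").encoding == "dosage_vector"
        assert ModelSpec(name="DNNGP").encoding == "pca_150"
        assert ModelSpec(name="SoyDNGP").encoding == "soy_3xSxS"

    def test_roundtrip_dict(self):
        s = ModelSpec(name="GBDT", hyperparams={"n_estimators": 10}, seed=3)
        assert ModelSpec.from_dict(s.to_dict()) == s


class TestPoolContract:
    def test_seeded_rf_determinism(self, additive_data):
        x, y = additive_data
        preds = []
        for _ in range(2):
            m = build_model(ModelSpec(name="RF", seed=1,
                                      hyperparams={"n_estimators": 30}))
            m.fit(x, y)
            preds.append(m.predict(x))
        assert np.array_equal(preds[0], preds[1])

    @pytest.mark.parametrize("name", MODEL_NAMES[:-1])  # EnvSE needs env input
    def test_beats_the_mean(self, name, additive_data):
        x, y = additive_data
        hp = {}
        if name in ("RF", "GBDT"):
            hp = {"n_estimators": 60}
        if name == "XGBoost":
            hp = {"max_iter": 60}
        spec = ModelSpec(name=name, seed=0, hyperparams=hp)
        m = build_model(spec)
        xe = _encode_for(name, x)
        if spec.is_deep:
            m.fit(xe, y, config=TrainConfig(max_epochs=60, patience=60, batch_size=32))
        else:
            m.fit(xe, y)
        mse = float(np.mean((m.predict(xe) - y) ** 2))
        assert mse < y.var()

    def test_envse_beats_the_mean(self, additive_data):
        x, y = additive_data
        rng = np.random.default_rng(0)
        e = rng.normal(size=(x.shape[0], 22))
        m = build_model(ModelSpec(name="EnvSE", seed=0))
        m.fit((x, e), y, config=TrainConfig(max_epochs=60, patience=60, batch_size=32))
        mse = float(np.mean((m.predict((x, e)) - y) ** 2))
        assert mse < y.var()


class TestDeepGSContract:
    def test_eval_forward_deterministic(self, additive_data):
        x, y = additive_data
        m = DeepGSNet(seed=0)
        m.fit(x, y, config=TrainConfig(max_epochs=2, batch_size=32))
        assert np.array_equal(m.predict(x), m.predict(x))

    def test_default_dropout_rate(self):
        assert DeepGSNet().dropout == 0.05

    def test_output_shape_and_structure(self, additive_data):
        x, y = additive_data
        m = DeepGSNet(seed=0)
        m.fit(x[:8], y[:8], config=TrainConfig(max_epochs=1, batch_size=8))
        out = m.net_forward(m._prep(x[:5]), train=False)
        assert out.shape == (5, 1)
        assert m.conv_layer_count == 1

    def test_too_short_input_rejected(self):
        m = DeepGSNet(seed=0)
        with pytest.raises(ValueError, match="kernel"):
            m.fit(np.zeros((4, 10)), np.zeros(4),
                  config=TrainConfig(max_epochs=1, batch_size=4))


class TestDLGWASContract:
    def test_branch_shapes_equal_before_merge(self, additive_data):
        x, y = additive_data
        xo = _encode_for("DLGWAS", x)
        m = DLGWASNet(seed=0)
        m.fit(xo[:8], y[:8], config=TrainConfig(max_epochs=1, batch_size=8))
        ya = m.branch_a.forward(xo[:3], train=False)
        yb = m.branch_b.forward(xo[:3], train=False)
        assert ya.shape == yb.shape

    def test_zeroed_branch_equals_single_branch(self, additive_data):
        x, y = additive_data
        xo = _encode_for("DLGWAS", x)
        m = DLGWASNet(seed=0)
        m.fit(xo[:16], y[:16], config=TrainConfig(max_epochs=1, batch_size=8))
        m.branch_b.w.value[...] = 0.0
        m.branch_b.b.value[...] = 0.0
        full = m.net_forward(xo[:4], train=False)
        single = m.head.forward(m.branch_a.forward(xo[:4], train=False), train=False)
        assert np.allclose(full, single)

    def test_eval_deterministic(self, additive_data):
        x, y = additive_data
        xo = _encode_for("DLGWAS", x)
        m = DLGWASNet(seed=0)
        m.fit(xo[:16], y[:16], config=TrainConfig(max_epochs=1, batch_size=8))
        assert np.array_equal(m.predict(xo), m.predict(xo))


class TestDNNGPContract:
    def test_three_conv_layers_and_one_dropout(self, additive_data):
        x, y = additive_data
        xp = _encode_for("DNNGP", x)
        m = DNNGPNet(seed=0)
        m.fit(xp[:16], y[:16], config=TrainConfig(max_epochs=1, batch_size=8))
        assert m.conv_layer_count == 3
        assert m.dropout_layer_count == 1

    def test_non_three_channel_schedule_rejected(self):
        with pytest.raises(ValueError, match="three"):
            DNNGPNet(channels=(64, 32))

    def test_batch_of_seven(self, additive_data):
        x, y = additive_data
        xp = _encode_for("DNNGP", x)
        m = DNNGPNet(seed=0)
        m.fit(xp[:16], y[:16], config=TrainConfig(max_epochs=1, batch_size=8))
        out = m.net_forward(m._prep(xp[:7]), train=False)
        assert out.shape == (7, 1)


class TestSoyDNGPContract:
    def test_accepts_s8(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, (12, 64)).astype(float)
        xs = _encode_for("SoyDNGP", x)
        assert xs.shape == (12, 3, 8, 8)
        m = SoyDNGPNet(seed=0)
        m.fit(xs, rng.normal(size=12), config=TrainConfig(max_epochs=1, batch_size=6))
        assert m.predict(xs).shape == (12,)

    def test_channel_schedule_independent_of_s(self):
        m8 = SoyDNGPNet(seed=0)
        m16 = SoyDNGPNet(seed=0)
        assert m8.channel_schedule == m16.channel_schedule
        rng = np.random.default_rng(0)
        for m, s in ((m8, 8), (m16, 16)):
            x = np.zeros((2, 3, s, s))
            x[:, 0] = 1.0
            m.fit(x, np.zeros(2), config=TrainConfig(max_epochs=1, batch_size=2))
        convs8 = [lay.w.value.shape[0] for lay in m8.net.layers if hasattr(lay, "w")
                  and lay.w.value.ndim == 4]
        convs16 = [lay.w.value.shape[0] for lay in m16.net.layers if hasattr(lay, "w")
                   and lay.w.value.ndim == 4]
        assert convs8 == convs16

    def test_eval_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, (10, 81)).astype(float)
        xs = _encode_for("SoyDNGP", x)
        m = SoyDNGPNet(seed=0)
        m.fit(xs, rng.normal(size=10), config=TrainConfig(max_epochs=1, batch_size=5))
        assert np.array_equal(m.predict(xs), m.predict(xs))


class TestEnvSEContract:
    @pytest.fixture()
    def fitted(self, additive_data):
        x, y = additive_data
        rng = np.random.default_rng(0)
        e = rng.normal(size=(x.shape[0], 22))
        m = EnvSENet(seed=0)
        m.fit((x, e), y, config=TrainConfig(max_epochs=3, batch_size=32))
        return m, x, e

    def test_embedding_dimension_is_64(self, fitted):
        m, x, e = fitted
        emb = m.env_mlp.forward(e[:4], train=False)
        assert emb.shape == (4, 64)

    def test_gates_pinned_to_one_reproduce_backbone(self, fitted):
        m, x, e = fitted
        m.gate_override = 1.0
        pinned = m.predict((x, e))
        m.gate_override = None
        assert np.array_equal(pinned, m.backbone_forward(x))

    def test_same_genotype_different_env_may_differ(self, fitted):
        m, x, e = fitted
        xg = np.tile(x[:1], (2, 1))
        ee = np.stack([e[0], e[1] + 5.0])
        out = m.predict((xg, ee))
        assert out[0] != out[1]

    def test_identical_env_identical_output(self, fitted):
        m, x, e = fitted
        xg = np.tile(x[:1], (2, 1))
        ee = np.tile(e[:1], (2, 1))
        out = m.predict((xg, ee))
        assert out[0] == out[1]

    def test_mismatched_env_width_rejected(self, fitted):
        m, x, e = fitted
        with pytest.raises(ValueError, match="length"):
            m.predict((x, e[:, :5]))


class TestAggregateEnv:
    def test_biweekly_28_days(self, rng):
        arr = rng.normal(size=(28, 11))
        v = aggregate_env(arr, mode="biweekly")
        assert len(v.values) == 22
        assert v.n_bins == 2

    def test_constant_series_all_modes_agree(self):
        arr = np.full((28, 11), 3.5)
        for mode in ("daily", "weekly", "biweekly"):
            v = aggregate_env(arr, mode=mode)
            assert np.allclose(v.values, 3.5)

    def test_weekly_matches_hand_binning(self, rng):
        arr = rng.normal(size=(17, 11))  # 2 full weeks + 3-day partial bin
        v = aggregate_env(arr, mode="weekly")
        expected = np.concatenate([
            arr[:7].mean(axis=0), arr[7:14].mean(axis=0), arr[14:].mean(axis=0)
        ])
        assert np.allclose(v.values, expected)
        assert v.n_bins == 3

    def test_daily_preserves_values(self, rng):
        arr = rng.normal(size=(5, 11))
        v = aggregate_env(arr, mode="daily")
        assert np.array_equal(v.values, arr.ravel())

    def test_window_truncation(self, rng):
        arr = rng.normal(size=(30, 11))
        v = aggregate_env(arr, mode="weekly", window_days=14)
        assert v.n_bins == 2

    def test_invalid_mode(self):
        with pytest.raises(ValueError, match="mode"):
            aggregate_env(np.zeros((7, 11)), mode="monthly")

    def test_feature_vector_length_invariant(self):
        with pytest.raises(ValueError, match="length"):
            EnvFeatureVector(env_id="e", values=np.zeros(10), mode="daily", n_bins=1)

    def test_read_env_csv(self, tmp_path, rng):
        rows = []
        for env in ("e1", "e2"):
            for d in range(3):
                rows.append({"env": env, "date": f"2024-01-0{d+1}",
                             **{v: float(d) for v in ENV_VARIABLES}})
        path = tmp_path / "env.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        series = read_env_csv(path)
        assert set(series) == {"e1", "e2"}
        assert series["e1"].shape == (3, 11)
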