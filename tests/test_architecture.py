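"""Configuration registry and network builder."""
import warnings

import numpy as np
import pytest

from seizurenet.architecture import (
    RNN_TYPES,
    STUDY_IDS,
    ConstructionError,
    ModelConfig,
    UnitConfig,
    ablate,
    build_model,
    get_config,
    iter_combinations,
    load_registry,
)

from _oracles import INPUT_LENGTHS, PUBLISHED_UNITS

def quiet_get_config(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return get_config(*args, **kwargs)


class TestRegistry:
    def test_all_60_combinations_resolve(self):
        combos = list(iter_combinations())
        assert len(combos) == 60
        for study, task, kind in combos:
            model, train = quiet_get_config(study, task, kind)
            assert model.rnn_type == kind
            assert train.batch_size == 64 and train.folds == 5

    def test_unit_stacks_match_published_table(self):
        for (study, task), units in PUBLISHED_UNITS.items():
            model, _ = quiet_get_config(study, task, "lstm")
            assert [[u.conv_filters, u.rnn_units] for u in model.units] \
                == units, (study, task)

    def test_spot_configs(self):
        model, train = quiet_get_config(1, "A-E", "BiLSTM")
        assert [[u.conv_filters, u.rnn_units] for u in model.units] \
            == [[32, 16], [16, 8]]
        assert model.units[0].kernel_size == 2
        assert model.dense_units == (100,)
        assert train.epochs == 50 and train.batch_size == 64

        model, _ = quiet_get_config(3, "AB-C-D-E", "BiLSTM")
        assert len(model.units) == 4

        model, _ = quiet_get_config(6, "A-E", "gru")
        assert model.dropout_rate is None and len(model.units) == 1

    def test_kernel_size_exceptions(self):
        for study, task, kernel in [(2, "AB-C-D-E", 4), (2, "A-B-C-D-E", 4),
                                    (5, "AB-C-D-E", 4), (5, "A-B-C-D-E", 8),
                                    (1, "A-E", 2), (5, "AB-CD-E", 2)]:
            model, _ = quiet_get_config(study, task, "lstm")
            assert all(u.kernel_size == kernel for u in model.units), \
                (study, task)

    def test_incomplete_configs_flagged_with_warning(self):
        with pytest.warns(UserWarning, match="no published value"):
            model, _ = get_config(4, "A-B-C-D-E", "lstm")
        assert "dense" in model.incomplete
        assert model.dense_units == (100,)  # documented fallback

    def test_unknown_combinations_raise_lookup(self):
        with pytest.raises(LookupError):
            quiet_get_config(7, "A-E", "lstm")
        with pytest.raises(Exception):
            quiet_get_config(1, "A-C", "lstm")
        with pytest.raises(LookupError):
            quiet_get_config(1, "A-E", "transformer")

    def test_overrides_replace_fields(self):
        model, _ = quiet_get_config(4, "A-B-C-D-E", "lstm",
                                    overrides={"dense": [64, 32]})
        assert model.dense_units == (64, 32)
        assert "dense" not in model.incomplete

    def test_registry_validates(self):
        registry = load_registry()
        assert sorted(registry["studies"]) == list(STUDY_IDS)


class TestBuildModel:
    def test_layer_sequence_for_two_unit_config(self):
        model_cfg, _ = quiet_get_config(1, "A-E", "lstm")
        net = build_model(model_cfg, 4097, seed=0)
        assert net.layer_names() == [
            "conv1d", "bilstm", "avgpool1d", "dropout",
            "conv1d", "bilstm", "avgpool1d",
            "flatten", "dense", "dense_softmax"]

    def test_no_dropout_layers_when_rate_none(self):
        model_cfg, _ = quiet_get_config(6, "A-E", "lstm")
        net = build_model(model_cfg, 178, seed=0)
        assert "dropout" not in net.layer_names()

    def test_probability_simplex_output(self):
        rng = np.random.default_rng(0)
        for study in (5, 6):
            for task in ("A-E", "AB-CD-E", "A-B-C-D-E"):
                for kind in RNN_TYPES:
                    cfg, _ = quiet_get_config(study, task, kind)
                    net = build_model(cfg, 178, seed=1)
                    x = rng.standard_normal((3, 178, 1)).astype(np.float32)
                    p = net.forward(x)
                    assert p.shape == (3, cfg.n_classes)
                    assert (p >= 0).all()
                    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_param_count_reproducible(self):
        cfg, _ = quiet_get_config(3, "AB-CD-E", "gru")
        assert build_model(cfg, 2048, seed=0).count_params() == \
            build_model(cfg, 2048, seed=99).count_params()

    def test_all_configs_build_at_study_input_length(self):
        for study, task, kind in iter_combinations():
            cfg, _ = quiet_get_config(study, task, kind)
            net = build_model(cfg, INPUT_LENGTHS[study], seed=0)
            n_units = len(cfg.units)
            names = net.layer_names()
            assert names.count("conv1d") == n_units
            assert names.count(f"bi{kind}") == n_units
            assert names.count("avgpool1d") == n_units

    def test_collapsed_time_axis_names_stage(self):
        cfg, _ = quiet_get_config(3, "AB-C-D-E", "lstm")  # four units
        with pytest.raises(ConstructionError, match="unit"):
            build_model(cfg, 16, seed=0)

    def test_empty_units_rejected(self):
        with pytest.raises(ConstructionError):
            ModelConfig(units=(), dense_units=(10,), n_classes=2)


class TestAblate:
    def test_drop_conv_removes_all_conv_stages(self):
        cfg, _ = quiet_get_config(1, "A-E", "lstm")
        net = build_model(ablate(cfg, "conv"), 4097, seed=0)
        names = net.layer_names()
        assert names.count("conv1d") == 0
        assert names.count("bilstm") == 2

    def test_drop_rnn_removes_all_rnn_stages(self):
        cfg, _ = quiet_get_config(1, "A-E", "lstm")
        net = build_model(ablate(cfg, "rnn"), 4097, seed=0)
        names = net.layer_names()
        assert names.count("conv1d") == 2
        assert names.count("bilstm") == 0

    def test_ablated_models_have_fewer_parameters(self):
        # conv removal shrinks every config with >= 1 conv stage
        cfg, _ = quiet_get_config(1, "AB-CD-E", "lstm")
        full = build_model(cfg, 4097, seed=0).count_params()
        assert build_model(ablate(cfg, "conv"), 4097, seed=0) \
            .count_params() < full
        # rnn removal shrinks the two-unit binary config, whose Bi-RNN
        # output width equals its conv width
        cfg, _ = quiet_get_config(1, "A-E", "lstm")
        full = build_model(cfg, 4097, seed=0).count_params()
        assert build_model(ablate(cfg, "rnn"), 4097, seed=0) \
            .count_params() < full

    def test_unknown_drop_kind_rejected(self):
        cfg, _ = quiet_get_config(1, "A-E", "lstm")
        for bad in ("pool", "flatten", "dense"):
            with pytest.raises(ValueError, match="unknown ablation"):
                ablate(cfg, bad)

    def test_training_settings_unchanged(self):
        cfg, _ = quiet_get_config(2, "B-E", "gru")
        dropped = ablate(cfg, "conv")
        assert dropped.dense_units == cfg.dense_units
        assert dropped.dropout_rate == cfg.dropout_rate
        assert dropped.units == cfg.units
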