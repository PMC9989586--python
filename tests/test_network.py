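"""Architecture geometry, ablation lattice, complexity, feature dumps."""

import itertools

import numpy as np
import pytest

from egtransunet import (
    ComplexityReport,
    ConfigurationError,
    ModelConfig,
    build_model,
    complexity,
    dump_feature_maps,
)
from egtransunet.nn import Tensor

TINY = dict(input_size=(64, 64), base_width=8)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ModelConfig(input_size=(100, 96))  # not divisible by 16
    with pytest.raises(ConfigurationError):
        ModelConfig(base_width=0, input_size=(64, 64))
    with pytest.raises(ConfigurationError):
        ModelConfig(input_size=(64, 64), attention_axis="diag")


def test_tiny_model_forward_smoke():
    model = build_model(ModelConfig(**TINY), seed=0).eval()
    x = np.random.default_rng(0).random((2, 3, 64, 64))
    out = model(Tensor(x))
    assert out.shape == (2, 1, 64, 64)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0


def test_encoder_stage_spatial_geometry():
    """Stage s output is input_size / 2^s; decoder doubles back up."""
    model = build_model(ModelConfig(**TINY), seed=1).eval()
    record = {}
    model(np.zeros((3, 64, 64)), record=record)
    for s, name in enumerate(["enc1", "enc2", "enc3", "enc4"], start=1):
        assert record[name].shape[-2:] == (64 // 2 ** s, 64 // 2 ** s)
    for d, name in enumerate(["dec1", "dec2", "dec3", "dec4"], start=1):
        assert record[name].shape[-2:] == (64 // 2 ** (4 - d), 64 // 2 ** (4 - d))


def test_wrong_input_size_raises():
    model = build_model(ModelConfig(**TINY), seed=0)
    with pytest.raises(ValueError, match="resize"):
        model(np.zeros((3, 80, 80)))


def test_batch_independence_in_eval_mode():
    model = build_model(ModelConfig(**TINY), seed=2).eval()
    x = np.random.default_rng(1).random((1, 3, 64, 64))
    pair = np.concatenate([x, x])
    out = model(Tensor(pair)).data
    assert np.array_equal(out[0], out[1])


def test_forward_determinism_fixed_weights():
    model = build_model(ModelConfig(**TINY), seed=3).eval()
    x = np.random.default_rng(2).random((1, 3, 64, 64))
    assert np.array_equal(model(Tensor(x)).data, model(Tensor(x)).data)


def test_seeded_builds_are_identical():
    m1 = build_model(ModelConfig(**TINY), seed=4)
    m2 = build_model(ModelConfig(**TINY), seed=4)
    for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
        assert n1 == n2 and np.array_equal(p1.data, p2.data)


def _variant(pem, csa, sga):
    return ModelConfig(use_pem=pem, use_csa=csa, use_sga=sga, **TINY)


def test_ablation_switches_change_topology():
    baseline = build_model(_variant(False, False, False), seed=0)
    full = build_model(_variant(True, True, True), seed=0)
    assert baseline.pem is None and baseline.csa is None and baseline.sga is None
    assert full.pem is not None and full.csa is not None and full.sga is not None
    # disabled CSA means the bottleneck passes through untouched
    record = {}
    baseline.eval()(np.zeros((3, 64, 64)), record=record)
    assert np.array_equal(record["csa"], record["enc4"])


def test_parameter_count_ordering_full_vs_single_off_vs_baseline():
    counts = {
        flags: build_model(_variant(*flags), seed=0).n_parameters()
        for flags in itertools.product([False, True], repeat=3)
    }
    full = counts[(True, True, True)]
    base = counts[(False, False, False)]
    for off in [(False, True, True), (True, False, True), (True, True, False)]:
        assert base < counts[off] < full


def test_ablation_lattice_monotone_params_and_macs():
    """Params and MACs are monotone under the switch partial order (8 variants)."""
    reports = {
        flags: complexity(_variant(*flags))
        for flags in itertools.product([False, True], repeat=3)
    }
    for a in reports:
        for b in reports:
            if all(x <= y for x, y in zip(a, b)) and a != b:
                assert reports[a].parameter_count < reports[b].parameter_count
                assert reports[a].mac_count < reports[b].mac_count
    # qualitative ordering: baseline < (+CSA only) < full
    base = reports[(False, False, False)].mac_count
    csa_only = reports[(False, True, False)].mac_count
    full = reports[(True, True, True)].mac_count
    assert base < csa_only < full


def test_complexity_report_is_positive():
    rep = complexity(ModelConfig(**TINY))
    assert isinstance(rep, ComplexityReport)
    assert rep.parameter_count > 0 and rep.mac_count > 0


def test_dump_feature_maps_contracts():
    model = build_model(ModelConfig(**TINY), seed=5)
    x = np.random.default_rng(3).random((3, 64, 64))
    snaps = dump_feature_maps(model, x, ["dec1", "dec2", "dec3", "dec4"])
    sizes = [snaps[f"dec{i}"].shape[-1] for i in range(1, 5)]
    assert sizes == [8, 16, 32, 64]  # doubling decoder geometry
    pem_pair = dump_feature_maps(model, x, ["pem_in", "pem_out"])
    assert pem_pair["pem_in"].shape == pem_pair["pem_out"].shape
    sga_snap = dump_feature_maps(model, x, ["sga"])["sga"]
    c3 = model.config.stage_channels[2]
    assert sga_snap.shape[0] == 2 * c3  # C_low + C_high before projection
    with pytest.raises(KeyError):
        dump_feature_maps(model, x, ["bottleneck7"])
    no_sga = build_model(_variant(True, True, False), seed=5)
    with pytest.raises(KeyError):
        dump_feature_maps(no_sga, x, ["sga"])


def test_feature_grid_png(tmp_path):
    from egtransunet import save_feature_grid

    model = build_model(ModelConfig(**TINY), seed=6)
    snap = dump_feature_maps(model, np.zeros((3, 64, 64)), ["enc1"])["enc1"]
    out = tmp_path / "enc1.png"
    save_feature_grid(snap, out)
    assert out.exists() and out.stat().st_size > 0


@pytest.mark.parametrize("size", [(320, 320)])
def test_full_resolution_geometry(size):
    """3x320x320 in -> encoder 160/80/40/20, output 1x320x320 in [0, 1]."""
    cfg = ModelConfig(input_size=size)
    model = build_model(cfg, seed=0).eval()
    record = {}
    x = np.random.default_rng(4).random((1, 3, *size))
    out = model(Tensor(x), record=record)
    assert [record[f"enc{s}"].shape[-1] for s in (1, 2, 3, 4)] == [160, 80, 40, 20]
    assert out.shape == (1, 1, 320, 320)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
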