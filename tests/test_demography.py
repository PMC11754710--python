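import numpy as np
import pytest

from rangecoal.demography import (
    MODEL_NAMES,
    AdmixtureEvent,
    DemeSpec,
    DemographicModel,
    MergeEvent,
    ParameterSpec,
    SizeChangeEvent,
    build_model,
    eval_expr,
    model_catalogue,
    validate_event_order,
)


# ---------------------------------------------------------------------------
# expression mini-language


def test_eval_expr_basics():
    env = {"N_Pgal": 20_000.0, "THYB_GAL": 30.0}
    assert eval_expr(5, env) == 5.0
    assert eval_expr("N_Pgal", env) == 20_000.0
    assert eval_expr("0.005 * N_Pgal", env) == 100.0
    assert eval_expr("max(THYB_GAL - 50, 0)", env) == 0.0
    assert eval_expr("min(2 + 3, 4)", env) == 4.0
    assert eval_expr("-THYB_GAL / 3", env) == -10.0


def test_eval_expr_rejects_unsafe_or_unbound():
    with pytest.raises(KeyError):
        eval_expr("UNKNOWN", {})
    with pytest.raises(ValueError):
        eval_expr("__import__('os')", {})
    with pytest.raises(ValueError):
        eval_expr("pow(2, 10)", {})


# ---------------------------------------------------------------------------
# catalogue census


def test_catalogue_has_thirteen_specifications():
    cat = model_catalogue()
    assert len(cat) == 13
    assert sum(m.n_demes == 3 for m in cat) == 3
    assert sum(m.n_demes == 4 for m in cat) == 10
    labels = [(m.name, m.submodel) for m in cat]
    assert ("4-dicho", "a") in labels and ("4-dicho", "b") in labels
    assert ("4-dicho+mig", "a") in labels and ("4-dicho+mig", "b") in labels
    assert len(set(labels)) == 13


def test_every_named_model_builds():
    for name in MODEL_NAMES:
        m = build_model(name)
        assert m.k == len(m.params) > 0
        assert all(p.low < p.high for p in m.params)


def test_unknown_model_name_lists_valid_names():
    with pytest.raises(ValueError, match="3-dicho"):
        build_model("5-ring")


def test_gene_flow_variants_add_two_rate_parameters():
    for base, mig in [
        ("3-dicho", "3-dicho+mig"),
        ("4-dicho", "4-dicho+mig"),
        ("4-hybGALearly", "4-hybGALearly+mig"),
    ]:
        assert build_model(mig).k == build_model(base).k + 2


def test_default_sample_sizes():
    m3 = build_model("3-dicho")
    assert m3.sample_sizes == {"Pgal": 12, "Pnig": 16, "Pspi": 32}
    m4 = build_model("4-dicho")
    assert m4.sample_sizes == {"Pgal": 12, "Pnig": 16, "PspE": 24, "PspW": 8}
    small = build_model("3-dicho", sample_sizes={"Pspi": 8})
    assert small.sample_sizes["Pspi"] == 8


def test_root_divergence_time_range():
    for m in model_catalogue():
        (p,) = [p for p in m.params if p.name == "TDIV_ANC"]
        assert (p.low, p.high) == (42_000.0, 139_000.0)
        assert p.kind == "time" and p.scale == "linear"


def test_size_and_migration_parameters_are_log_scale():
    m = build_model("3-dicho+mig")
    for p in m.params:
        if p.kind in ("size", "rate"):
            assert p.scale == "log"
            assert (p.low, p.high) == ((1e2, 2e5) if p.kind == "size" else (1e-8, 1e-2))


def test_hybrid_models_carry_bottleneck_size_changes():
    for name, hybrid, present in [
        ("3-hybGAL", "Pgal", "N_Pgal"),
        ("4-hybSPW", "PspW", "N_PspW"),
        ("4-hybGALlate", "Pgal", "N_Pgal"),
    ]:
        m = build_model(name)
        bn = [e for e in m.events if isinstance(e, SizeChangeEvent) and e.role == "bottleneck"]
        assert len(bn) == 2
        env = {p.name: (p.low + p.high) / 2 for p in m.params}
        conc = sorted([ (eval_expr(e.t, env), eval_expr(e.new_N, env)) for e in bn ])
        t_hyb = env[[p.name for p in m.params if p.name.startswith("THYB")][0]]
        n_now = env[present]
        assert conc[0] == (max(t_hyb - 50, 0), pytest.approx(0.005 * n_now))
        assert conc[1] == (t_hyb, pytest.approx(n_now))


def test_background_migration_topology():
    m3 = build_model("3-dicho")
    assert set(m3.migration) == {("Pnig", "Pspi"), ("Pspi", "Pnig")}
    m4 = build_model("4-hybSPW")
    assert set(m4.migration) == {
        ("Pnig", "PspE"), ("PspE", "Pnig"), ("PspW", "PspE"), ("PspE", "PspW")
    }
    mig = build_model("3-dicho+mig")
    assert ("Pgal", "Pspi") in mig.migration and ("Pspi", "Pgal") in mig.migration


def test_submodels_encode_opposite_divergence_orders():
    a = build_model("4-dicho", "a")
    b = build_model("4-dicho", "b")
    assert ("TDIV_SPW", "TDIV_GAL") in a.constraints
    assert ("TDIV_GAL", "TDIV_SPW") in b.constraints
    with pytest.raises(ValueError):
        build_model("4-dicho", "c")


def test_overrides_fix_parameters():
    m = build_model("3-dicho", overrides={"N_Pgal": 20_000.0, "TDIV_GAL": 15_000.0})
    assert "N_Pgal" not in m.param_names()
    assert m.fixed["N_Pgal"] == 20_000.0
    assert m.k == build_model("3-dicho").k - 2
    with pytest.raises(ValueError, match="range"):
        build_model("3-dicho", overrides={"N_Pgal": 1e7})
    with pytest.raises(ValueError, match="unknown"):
        build_model("3-dicho", overrides={"N_BOGUS": 1.0})


def test_bind_accepts_dict_and_vector():
    m = build_model("3-dicho", overrides={"TDIV_ANC": 60_000.0})
    vals = {p.name: (p.low + p.high) / 2 for p in m.params}
    env_d = m.bind(vals)
    env_v = m.bind([vals[n] for n in m.param_names()])
    assert env_d == env_v
    assert env_d["TDIV_ANC"] == 60_000.0
    with pytest.raises(ValueError):
        m.bind([1.0, 2.0])  # wrong length


def test_json_round_trip():
    for m in model_catalogue():
        back = DemographicModel.from_json(m.to_json())
        assert back.to_json() == m.to_json()
        assert back.deme_names == m.deme_names
        assert back.param_names() == m.param_names()
        assert back.constraints == m.constraints


# ---------------------------------------------------------------------------
# event-order validation


def _dicho_params(**over):
    base = dict(
        N_Pgal=20_000.0, N_Pnig=30_000.0, N_Pspi=50_000.0, N_ANC=40_000.0,
        N_ANC_GN=30_000.0, TDIV_GAL=15_000.0, TDIV_ANC=60_000.0,
        MIG_Pnig_Pspi=1e-5, MIG_Pspi_Pnig=1e-5,
    )
    base.update(over)
    return base


def test_validate_accepts_consistent_vector():
    m = build_model("3-dicho")
    assert validate_event_order(m, _dicho_params()) == []


def test_validate_flags_child_older_than_root():
    m = build_model("3-dicho")
    v = validate_event_order(m, _dicho_params(TDIV_GAL=70_000.0))
    assert any("TDIV_GAL" in s for s in v)


def test_validate_flags_tied_divergence_times():
    # a time tie would let the root merge execute before the child merge,
    # stranding lineages in an extinct deme
    m = build_model("3-dicho")
    v = validate_event_order(m, _dicho_params(TDIV_GAL=60_000.0))
    assert any("TDIV_GAL" in s for s in v)


def test_validate_flags_fixed_time_beyond_root():
    m = build_model("3-dicho", overrides={"TDIV_GAL": 15_000.0})
    params = {k: v for k, v in _dicho_params().items() if k != "TDIV_GAL"}
    params["TDIV_ANC"] = 42_000.0
    assert validate_event_order(m, params) == []
    m2 = build_model("3-hybGAL")
    bad = dict(
        N_Pgal=20_000.0, N_Pnig=30_000.0, N_Pspi=50_000.0, N_ANC=40_000.0,
        THYB_GAL=100_000.0, ALPHA_gal=0.5, TDIV_ANC=60_000.0,
        MIG_Pnig_Pspi=1e-5, MIG_Pspi_Pnig=1e-5,
    )
    assert any("THYB_GAL" in s for s in validate_event_order(m2, bad))


def test_validate_flags_negative_time():
    m = DemographicModel(
        name="toy",
        demes=[DemeSpec("A", 1000.0, 4), DemeSpec("B", 1000.0, 4)],
        events=[MergeEvent(t="T", source="A", dest="B")],
        migration={},
        params=[ParameterSpec("T", -10.0, 10.0)],
    )
    assert validate_event_order(m, {"T": -5.0})
    assert validate_event_order(m, {"T": 5.0}) == []


def test_validate_flags_event_inside_bottleneck_window():
    demes = [DemeSpec("A", 1000.0, 4), DemeSpec("B", 1000.0, 4), DemeSpec("C", 1000.0, 4)]
    mk = lambda t_size: DemographicModel(
        name="toy-hyb",
        demes=demes,
        events=[
            AdmixtureEvent(t=1000.0, hybrid="A", parent_a="B", parent_b="C", alpha=0.5),
            SizeChangeEvent(t=t_size, deme="A", new_N=500.0),
            MergeEvent(t=5000.0, source="C", dest="B"),
        ],
        migration={},
        params=[],
    )
    assert validate_event_order(mk(980.0), {})  # inside (950, 1000)
    assert validate_event_order(mk(900.0), {}) == []  # before the window


def test_bottleneck_window_clamped_at_zero():
    m = build_model("3-hybGAL")

    def bottleneck_start(t_hyb):
        params = dict(
            N_Pgal=20_000.0, N_Pnig=30_000.0, N_Pspi=50_000.0, N_ANC=40_000.0,
            THYB_GAL=t_hyb, ALPHA_gal=0.5, TDIV_ANC=60_000.0,
            MIG_Pnig_Pspi=1e-5, MIG_Pspi_Pnig=1e-5,
        )
        assert validate_event_order(m, params) == []
        env = m.bind(params)
        bn = [e for e in m.concrete_events(env) if getattr(e, "role", "") == "bottleneck"]
        assert bn[0].new_N == pytest.approx(0.005 * 20_000.0)
        return bn[0].t

    assert bottleneck_start(120.0) == 70.0
    assert bottleneck_start(30.0) == 0.0  # window truncated at the present


def test_admixture_hybrid_cannot_be_parent():
    with pytest.raises(ValueError):
        AdmixtureEvent(t=1.0, hybrid="A", parent_a="A", parent_b="B", alpha=0.5)


def test_migration_epochs_shut_off_extinct_demes():
    m = build_model("3-dicho")
    env = m.bind(_dicho_params())
    epochs = m.migration_epochs(env)
    assert epochs[0].rates  # extant epoch has the background rates
    last = epochs[-1]
    assert last.t_start >= 60_000.0 and last.rates == {}
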