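"""Domain types, design expansion, aggregation and payload serialization."""

import numpy as np
import pandas as pd
import pytest

from distreg import (
    Covariate,
    DDArray,
    ModelSpec,
    Payload,
    PayloadError,
    ProtocolError,
    SchemaError,
    SiteDataset,
    SpecError,
    aggregate_payloads,
    check_convergence,
    design_columns,
    expand_design,
    read_payload,
    write_payload,
)


def _spec(covs, family="linear", outcome="y", **kw):
    return ModelSpec(family=family, outcome=outcome, covariates=covs, **kw)


# ---------------------------------------------------------------------------
# ModelSpec validation


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(family="poisson", outcome="y", covariates=[Covariate("x")]),
        dict(family="linear", outcome="y", covariates=[]),
        dict(family="cox", outcome="t", covariates=[Covariate("x")]),  # no event
        dict(family="linear", outcome="y", covariates=[Covariate("x")],
             convergence_epsilon=0.0),
        dict(family="linear", outcome="y", covariates=[Covariate("x")],
             max_iterations=0),
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(SpecError):
        ModelSpec(**kwargs)


def test_reference_level_must_be_declared():
    with pytest.raises(SpecError):
        Covariate("race", kind="categorical", levels=("a", "b"), reference="z")


def test_digest_is_stable_and_spec_sensitive():
    s1 = _spec([Covariate("x")])
    s2 = _spec([Covariate("x")])
    s3 = _spec([Covariate("x")], convergence_epsilon=0.5)
    assert s1.digest == s2.digest
    assert s1.digest != s3.digest


# ---------------------------------------------------------------------------
# Design expansion


def test_six_level_factor_yields_five_indicators():
    levels = ("white", "unknown", "aian", "asian", "black", "nhpi")
    spec = _spec([Covariate("race", kind="categorical", levels=levels,
                            reference="white")])
    df = pd.DataFrame({"race": list(levels), "y": np.zeros(6)})
    design = expand_design(SiteDataset("s1", df), spec)
    assert design.columns == [
        "(intercept)", "race[unknown]", "race[aian]", "race[asian]",
        "race[black]", "race[nhpi]",
    ]
    # each non-reference row lights exactly its own indicator
    assert np.array_equal(design.values[:, 1:],
                          np.vstack([np.zeros(5), np.eye(5)]))


def test_continuous_columns_pass_through_with_intercept():
    spec = _spec([Covariate("a"), Covariate("b")])
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0], "y": [0.0, 0.0]})
    design = expand_design(SiteDataset("s1", df), spec)
    assert np.array_equal(design.values,
                          [[1.0, 1.0, 3.0], [1.0, 2.0, 4.0]])


def test_three_level_dummy_coding():
    spec = _spec([Covariate("f", kind="categorical", levels=("a", "b", "c"),
                            reference="a")])
    df = pd.DataFrame({"f": ["a", "b", "c"], "y": np.zeros(3)})
    design = expand_design(SiteDataset("s1", df), spec)
    assert np.array_equal(design.values[:, 1:], [[0, 0], [1, 0], [0, 1]])


def test_unseen_level_raises_schema_error_naming_everything():
    spec = _spec([Covariate("f", kind="categorical", levels=("a", "b"),
                            reference="a")])
    df = pd.DataFrame({"f": ["a", "zzz"], "y": np.zeros(2)})
    with pytest.raises(SchemaError) as err:
        expand_design(SiteDataset("siteX", df), spec)
    msg = str(err.value)
    assert "siteX" in msg and "'f'" in msg and "zzz" in msg


def test_cox_design_has_no_intercept():
    spec = ModelSpec(family="cox", outcome="t", event="e",
                     covariates=[Covariate("x")])
    assert design_columns(spec) == ["x"]


def test_design_is_deterministic(small_sites, specs):
    a = expand_design(small_sites[0], specs["logistic"])
    b = expand_design(small_sites[0], specs["logistic"])
    assert a.columns == b.columns
    assert np.array_equal(a.values, b.values)


def test_missing_values_rejected():
    spec = _spec([Covariate("x")])
    df = pd.DataFrame({"x": [1.0, np.nan], "y": [0.0, 1.0]})
    with pytest.raises(SchemaError):
        expand_design(SiteDataset("s1", df), spec)


# ---------------------------------------------------------------------------
# Aggregation


def _payload(mat, site="s1", iteration=0, n=3, kind="k", digest="d"):
    return Payload(kind=kind, site_id=site, iteration=iteration, digest=digest,
                   n=n, components={"m": DDArray(mat)})


def test_single_payload_aggregates_to_itself():
    p = _payload(np.arange(4.0).reshape(2, 2))
    agg = aggregate_payloads([p])
    assert np.array_equal(agg.component("m"), p.component("m"))
    assert agg.n == p.n


def test_zero_payloads_sum_to_zero():
    ps = [_payload(np.zeros((4, 4)), site=f"s{i}") for i in range(3)]
    agg = aggregate_payloads(ps)
    assert np.all(agg.component("m") == 0)


def test_aggregation_matches_loop_accumulated_sum():
    rng = np.random.default_rng(0)
    mats = []
    for _ in range(3):
        a = rng.normal(size=(4, 4))
        mats.append(a + a.T)
    ps = [_payload(m, site=f"s{i}") for i, m in enumerate(mats)]
    agg = aggregate_payloads(ps)
    expected = np.zeros((4, 4))
    for m in mats:
        expected += m
    assert np.allclose(agg.component("m"), expected, rtol=0, atol=1e-14)
    assert agg.n == 9


def test_aggregation_order_invariance():
    rng = np.random.default_rng(1)
    ps = [_payload(rng.normal(size=(3, 3)), site=f"s{i}") for i in range(4)]
    fwd = aggregate_payloads(ps).component("m")
    rev = aggregate_payloads(ps[::-1]).component("m")
    assert np.array_equal(fwd, rev)


def test_iteration_mismatch_is_protocol_error():
    with pytest.raises(ProtocolError):
        aggregate_payloads(
            [_payload(np.zeros(2)), _payload(np.zeros(2), site="s2",
                                             iteration=1)]
        )


def test_shape_mismatch_is_protocol_error():
    with pytest.raises(ProtocolError):
        aggregate_payloads(
            [_payload(np.zeros(2)), _payload(np.zeros(3), site="s2")]
        )


def test_keyed_blocks_union_merge():
    p1 = Payload(kind="k", site_id="a", iteration=0, digest="d", n=1,
                 keyed={"ev": {3.0: 1.0, 5.0: 1.0}})
    p2 = Payload(kind="k", site_id="b", iteration=0, digest="d", n=1,
                 keyed={"ev": {5.0: 1.0, 9.0: 1.0}})
    agg = aggregate_payloads([p1, p2])
    assert agg.keyed["ev"] == {3.0: 1.0, 5.0: 2.0, 9.0: 1.0}


# ---------------------------------------------------------------------------
# Serialization


def _rich_payload(n=4):
    rng = np.random.default_rng(2)
    return Payload(
        kind="logistic.diagnostics", site_id="siteA", iteration=3, digest="abc",
        n=n,
        components={
            "g": DDArray(rng.normal(size=5), rng.normal(size=5) * 1e-20),
            "scalar": DDArray(np.array(np.pi)),
        },
        keyed={"ev": {1.0: 2.0, 365.0: 7.0}},
        stacked={"bins": rng.random((3, 4))},
    )


def test_payload_round_trip_exact(tmp_path):
    p = _rich_payload()
    path = tmp_path / "p.json"
    write_payload(p, path)
    q = read_payload(path)
    assert q.kind == p.kind and q.site_id == p.site_id
    assert q.iteration == p.iteration and q.n == p.n
    for name in p.components:
        assert np.array_equal(q.components[name].hi, p.components[name].hi)
        assert np.array_equal(q.components[name].lo, p.components[name].lo)
    assert q.keyed == p.keyed
    assert np.array_equal(q.stacked["bins"], p.stacked["bins"])


def test_empty_payload_round_trips(tmp_path):
    p = Payload(kind="k", site_id="s", iteration=0, digest="d", n=0,
                components={"m": DDArray(np.empty((0, 2)))},
                keyed={"ev": {}}, stacked={"bins": np.empty((0, 4))})
    path = tmp_path / "p.json"
    write_payload(p, path)
    q = read_payload(path)
    assert q.n == 0
    assert q.components["m"].shape == (0, 2)
    assert q.keyed["ev"] == {}
    assert q.stacked["bins"].shape == (0, 4)


def test_truncated_payload_raises_parse_error(tmp_path):
    p = _rich_payload()
    path = tmp_path / "p.json"
    write_payload(p, path)
    text = path.read_text()
    path.write_text(text[: len(text) // 2])
    with pytest.raises(PayloadError):
        read_payload(path)


def test_foreign_json_rejected(tmp_path):
    path = tmp_path / "x.json"
    path.write_text('{"rows": [[1, 2, 3]]}')
    with pytest.raises(PayloadError):
        read_payload(path)


# ---------------------------------------------------------------------------
# Convergence check


@pytest.mark.parametrize(
    "delta,expected",
    [(0.0, True), (0.009, True), (0.011, False)],
)
def test_convergence_criterion_boundaries(delta, expected):
    beta = np.zeros(3)
    new = beta.copy()
    new[1] = delta
    assert check_convergence(beta, new, 0.01) is expected


def test_convergence_length_mismatch():
    with pytest.raises(ProtocolError):
        check_convergence(np.zeros(2), np.zeros(3), 0.01)
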