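"""Posterior computation and assignment rules, against an exact oracle."""

import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comcatva.bayes_engine import (
    EngineSettings,
    assign_causes,
    assign_comcat,
    compute_posterior,
    process_dataset,
)
from comcatva.probbase import CategorySet, ProbBase
from comcatva.va_records import Response, VARecord

from conftest import make_posterior, posterior_oracle, random_probbase, random_record


def two_cat_pb(p_yes=(0.8, 0.2), prior=(0.5, 0.5)) -> ProbBase:
    cats = CategorySet("t", ("a", "b"))
    return ProbBase(
        category_set=cats,
        prior={"a": prior[0], "b": prior[1]},
        cond={
            ("I1", "yes"): {"a": p_yes[0], "b": p_yes[1]},
            ("I1", "no"): {"a": 1 - p_yes[0], "b": 1 - p_yes[1]},
        },
    )


class TestComputePosterior:
    def test_all_missing_returns_prior(self):
        pb = two_cat_pb(prior=(0.3, 0.7))
        rec = VARecord("D1", {"I1": Response.MISSING})
        post = compute_posterior(rec, pb)
        assert post.updates_applied == 0
        assert post.likelihood == {"a": 0.3, "b": 0.7}

    def test_single_yes_closed_form(self):
        # 0.5*0.8 / (0.5*0.8 + 0.5*0.2) = 0.8, to machine precision
        post = compute_posterior(VARecord("D1", {"I1": Response.YES}), two_cat_pb())
        assert post.likelihood["a"] == pytest.approx(0.8, abs=1e-15)
        assert post.likelihood["b"] == pytest.approx(0.2, abs=1e-15)
        assert post.updates_applied == 1

    def test_zero_conditional_annihilates_category(self):
        pb = two_cat_pb(p_yes=(0.0, 0.5))
        post = compute_posterior(VARecord("D1", {"I1": Response.YES}), pb)
        assert post.likelihood["a"] == 0.0
        assert post.likelihood["b"] == 1.0

    def test_all_categories_annihilated_is_degenerate(self):
        pb = two_cat_pb(p_yes=(0.0, 0.0))
        post = compute_posterior(VARecord("D1", {"I1": Response.YES}), pb)
        assert post.degenerate
        assert set(post.likelihood.values()) == {0.0}

    def test_absent_probbase_row_contributes_no_factor(self):
        cats = CategorySet("t", ("a", "b"))
        pb = ProbBase(category_set=cats, prior={"a": 0.5, "b": 0.5},
                      cond={("I1", "yes"): {"a": 0.8, "b": 0.2}})
        # NO row omitted -> NO response is non-informative
        post = compute_posterior(VARecord("D1", {"I1": Response.NO}), pb)
        assert post.updates_applied == 0
        assert post.likelihood == {"a": 0.5, "b": 0.5}

    def test_matches_oracle_on_mixed_record(self, rng):
        pb = random_probbase(rng, n_cats=3, n_indicators=4, allow_zero=False,
                             allow_tiny=False)
        rec = random_record(rng, pb)
        expected, degenerate = posterior_oracle(rec, pb)
        post = compute_posterior(rec, pb)
        assert post.degenerate == degenerate
        for c in pb.category_set.labels:
            assert post.likelihood[c] == pytest.approx(expected[c], abs=1e-9)

    def test_long_record_with_tiny_factors_does_not_underflow(self):
        # 400 indicators each contributing ~1e-3 would underflow a naive product
        cats = CategorySet("t", ("a", "b"))
        cond = {}
        for k in range(400):
            cond[(f"I{k}", "yes")] = {"a": 2e-3, "b": 1e-3}
        pb = ProbBase(category_set=cats, prior={"a": 0.5, "b": 0.5}, cond=cond)
        rec = VARecord("D1", {f"I{k}": Response.YES for k in range(400)})
        post = compute_posterior(rec, pb)
        assert not post.degenerate
        # (2e-3/1e-3)^400 dominates entirely
        assert post.likelihood["a"] == pytest.approx(1.0, abs=1e-12)


class TestAssignComcat:
    def test_dominant_category_assigned(self):
        dist = make_posterior({"traditions": 0.05, "emergencies": 0.60,
                               "recognition": 0.10, "resources": 0.10,
                               "health_systems": 0.10, "inevitability": 0.05})
        assert assign_comcat(dist).assigned == "emergencies"

    def test_exact_half_is_not_dominant(self):
        dist = make_posterior({"a": 0.5, "b": 0.3, "c": 0.2})
        assert assign_comcat(dist).assigned == "multiple"

    def test_no_dominance_yields_multiple(self):
        dist = make_posterior({"a": 0.30, "b": 0.30, "c": 0.20,
                               "d": 0.10, "e": 0.05, "f": 0.05})
        assert assign_comcat(dist).assigned == "multiple"

    def test_degenerate_yields_multiple(self):
        dist = make_posterior({"a": 0.0, "b": 0.0}, degenerate=True)
        assert assign_comcat(dist).assigned == "multiple"

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_outside_open_interval_rejected(self, threshold):
        dist = make_posterior({"a": 1.0, "b": 0.0})
        with pytest.raises(ValueError, match="threshold"):
            assign_comcat(dist, threshold=threshold)

    def test_custom_threshold_is_strict(self):
        dist = make_posterior({"a": 0.4, "b": 0.6})
        assert assign_comcat(dist, threshold=0.6).assigned == "multiple"
        assert assign_comcat(dist, threshold=0.59).assigned == "b"


class TestAssignCauses:
    def test_single_strong_cause(self):
        dist = make_posterior({"x": 0.9, "y": 0.06, "z": 0.04})
        out = assign_causes(dist, max_causes=3, report_threshold=0.1)
        assert out.ranked == [("x", 0.9)]
        assert out.indeterminate_residual == pytest.approx(0.1, abs=1e-12)

    def test_uniform_over_64_is_fully_indeterminate(self):
        dist = make_posterior({f"c{k}": 1 / 64 for k in range(64)})
        out = assign_causes(dist, report_threshold=0.1)
        assert out.ranked == []
        assert out.indeterminate_residual == pytest.approx(1.0, abs=1e-12)

    def test_matches_sort_truncate_oracle_on_crafted_distribution(self):
        liks = {"a": 0.35, "b": 0.25, "c": 0.20, "d": 0.15, "e": 0.05}
        dist = make_posterior(liks)
        out = assign_causes(dist, max_causes=3, report_threshold=0.1)
        # independent oracle: full sort, truncate, cumulative sum
        ordered = sorted(liks.items(), key=lambda kv: -kv[1])
        expected = [kv for kv in ordered if kv[1] >= 0.1][:3]
        assert out.ranked == expected
        assert out.indeterminate_residual == pytest.approx(
            1.0 - sum(p for _, p in expected), abs=1e-12)

    def test_degenerate_is_fully_indeterminate(self):
        dist = make_posterior({"a": 0.0, "b": 0.0}, degenerate=True)
        out = assign_causes(dist)
        assert out.ranked == [] and out.indeterminate_residual == 1.0

    def test_max_causes_below_one_rejected(self):
        with pytest.raises(ValueError, match="max_causes"):
            assign_causes(make_posterior({"a": 1.0}), max_causes=0)


class TestProcessDataset:
    def _records(self, rng, pb, n=10):
        return [random_record(rng, pb, record_id=f"D{k}") for k in range(n)]

    def test_causes_absent_without_cause_probbase(self, rng):
        pb = random_probbase(rng, 3, 5)
        outs = process_dataset(self._records(rng, pb), comcat_pb=pb)
        assert len(outs) == 10
        assert all(o.causes is None for o in outs)

    def test_comcat_outputs_independent_of_cause_processing(self, rng):
        comcat_pb = random_probbase(rng, 4, 6)
        cause_pb = random_probbase(rng, 5, 6)
        records = self._records(rng, comcat_pb)
        only = process_dataset(records, comcat_pb=comcat_pb)
        both = process_dataset(records, comcat_pb=comcat_pb, cause_pb=cause_pb)
        for a, b in zip(only, both):
            assert a.comcat.assigned == b.comcat.assigned
            assert a.comcat.distribution.likelihood == b.comcat.distribution.likelihood
        assert all(o.causes is not None for o in both)

    def test_permuting_records_permutes_outputs(self, rng):
        pb = random_probbase(rng, 3, 5)
        records = self._records(rng, pb)
        outs = {o.record_id: o.comcat.assigned for o in process_dataset(records, pb)}
        shuffled = list(records)
        random.Random(1).shuffle(shuffled)
        outs2 = {o.record_id: o.comcat.assigned
                 for o in process_dataset(shuffled, pb)}
        assert outs == outs2

    def test_settings_flow_through(self, rng):
        pb = random_probbase(rng, 3, 5, allow_zero=False, allow_tiny=False)
        records = self._records(rng, pb, n=5)
        outs = process_dataset(
            records, comcat_pb=pb, cause_pb=pb,
            settings=EngineSettings(max_causes=1, report_threshold=0.0),
        )
        assert all(len(o.causes.ranked) == 1 for o in outs)


# --- property tests ---------------------------------------------------------

@st.composite
def pb_and_record(draw):
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    n_cats = draw(st.integers(2, 5))
    n_ind = draw(st.integers(1, 8))
    pb = random_probbase(rng, n_cats, n_ind)
    rec = random_record(rng, pb)
    return pb, rec


@given(pb_and_record())
def test_posterior_normalizes_or_is_degenerate(case):
    pb, rec = case
    post = compute_posterior(rec, pb)
    if post.degenerate:
        assert set(post.likelihood.values()) == {0.0}
    else:
        assert math.isclose(sum(post.likelihood.values()), 1.0, abs_tol=1e-9)


@given(pb_and_record(), st.randoms(use_true_random=False))
def test_posterior_is_order_invariant(case, shuffler):
    pb, rec = case
    post = compute_posterior(rec, pb)
    items = list(rec.responses.items())
    shuffler.shuffle(items)
    shuffled = VARecord(rec.record_id, dict(items))
    assert compute_posterior(shuffled, pb).likelihood == post.likelihood


@given(pb_and_record(), st.floats(0.25, 4.0), st.integers(0, 7))
def test_posterior_is_scale_invariant(case, k, which):
    """Rescaling one conditional row by k>0 leaves the posterior unchanged."""
    pb, rec = case
    keys = list(pb.cond)
    key = keys[which % len(keys)]
    scaled_cond = {kk: dict(row) for kk, row in pb.cond.items()}
    # keep values in [0,1] after scaling so the ProbBase still validates
    k_eff = min(k, 1.0 / max(max(scaled_cond[key].values()), 1e-300))
    scaled_cond[key] = {c: v * k_eff for c, v in scaled_cond[key].items()}
    pb2 = ProbBase(category_set=pb.category_set, prior=dict(pb.prior), cond=scaled_cond)
    a = compute_posterior(rec, pb)
    b = compute_posterior(rec, pb2)
    assert a.degenerate == b.degenerate
    for c in pb.category_set.labels:
        assert b.likelihood[c] == pytest.approx(a.likelihood[c], abs=1e-9)


@given(st.integers(0, 2**31 - 1))
def test_favourable_yes_response_never_decreases_likelihood(seed):
    """Adding a YES whose conditional strictly favours c cannot lower c."""
    rng = np.random.default_rng(seed)
    pb = random_probbase(rng, 3, 4, allow_zero=False, allow_tiny=False)
    rec = random_record(rng, pb)
    target = pb.category_set.labels[0]
    before = compute_posterior(rec, pb)
    extra = "XNEW"
    cond = {k: dict(v) for k, v in pb.cond.items()}
    row = {c: 0.2 for c in pb.category_set.labels}
    row[target] = 0.9
    cond[(extra, "yes")] = row
    pb2 = ProbBase(category_set=pb.category_set, prior=dict(pb.prior), cond=cond)
    rec2 = VARecord(rec.record_id, {**rec.responses, extra: Response.YES})
    after = compute_posterior(rec2, pb2)
    if not before.degenerate and not after.degenerate:
        assert after.likelihood[target] >= before.likelihood[target] - 1e-12
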