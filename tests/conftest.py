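"""Shared fixtures and the independent posterior oracle.

The oracle recomputes the naive-Bayes posterior with exact rational
arithmetic (``fractions.Fraction`` over the float bit patterns), completely
independently of the engine's float/log-space code path.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import settings

from comcatva.probbase import CategorySet, ProbBase, make_synthetic_comcat_probbase
from comcatva.va_records import Response, VARecord

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def posterior_oracle(record: VARecord, pb: ProbBase) -> tuple[dict[str, float], bool]:
    """Exact-arithmetic naive-Bayes posterior; returns (likelihoods, degenerate)."""
    labels = pb.category_set.labels
    mass = {c: Fraction(pb.prior[c]) for c in labels}
    for ind, resp in record.substantive().items():
        row = pb.get(ind, "yes" if resp is Response.YES else "no")
        if row is None:
            continue
        for c in labels:
            mass[c] *= Fraction(row[c])
    total = sum(mass.values())
    if total == 0:
        return {c: 0.0 for c in labels}, True
    return {c: float(mass[c] / total) for c in labels}, False


def random_probbase(rng: np.random.Generator, n_cats: int, n_indicators: int,
                    allow_zero: bool = True, allow_tiny: bool = True) -> ProbBase:
    """A random small probbase exercising zeros, tiny values and missing NO rows."""
    labels = tuple(f"c{j}" for j in range(n_cats))
    prior_raw = rng.uniform(0.05, 1.0, size=n_cats)
    prior = {c: float(p) for c, p in zip(labels, prior_raw / prior_raw.sum())}
    cond: dict[tuple[str, str], dict[str, float]] = {}
    for k in range(n_indicators):
        ind = f"X{k:03d}"
        for resp in ("yes", "no"):
            if resp == "no" and rng.random() < 0.3:
                continue  # NO row omitted: negative responses non-informative
            row: dict[str, float] = {}
            for c in labels:
                u = rng.random()
                if allow_zero and u < 0.05:
                    row[c] = 0.0
                elif allow_tiny and u < 0.10:
                    row[c] = float(rng.uniform(1e-300, 1e-12))
                else:
                    row[c] = float(rng.uniform(0.0, 1.0))
            cond[(ind, resp)] = row
    return ProbBase(category_set=CategorySet("random", labels), prior=prior, cond=cond)


def random_record(rng: np.random.Generator, pb: ProbBase, record_id: str = "R") -> VARecord:
    responses = {}
    for ind in pb.indicator_ids:
        responses[ind] = rng.choice([Response.YES, Response.NO, Response.MISSING])
    return VARecord(record_id=record_id, responses=responses)


@pytest.fixture(scope="session")
def comcat_pb() -> ProbBase:
    return make_synthetic_comcat_probbase()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120416)


def make_posterior(likelihoods: dict[str, float], degenerate: bool = False):
    """Hand-built PosteriorDistribution for assignment-rule tests."""
    from comcatva.bayes_engine import PosteriorDistribution

    return PosteriorDistribution(
        category_set=CategorySet("t", tuple(likelihoods)),
        likelihood=dict(likelihoods),
        degenerate=degenerate,
    )
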