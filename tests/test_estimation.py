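"""Parameter-estimation arithmetic against the published cohort analysis."""

import pytest
from hypothesis import given, settings, strategies as st

import mddvuln as m
from mddvuln.estimation import EstimationError


def test_rescale_counts_cohort():
    f = m.rescale_counts(88, 136, 3, 227)
    # the published 0.3876 truncates the true 0.38767
    assert f.x == pytest.approx(0.3876, abs=1e-4)
    assert f.y == pytest.approx(0.5991, abs=1e-4)
    assert f.z == pytest.approx(0.0132, abs=1e-4)


@pytest.mark.parametrize(
    "counts, expected",
    [((0, 0, 10, 10), (0, 0, 1)), ((1, 1, 2, 4), (0.25, 0.25, 0.5))],
)
def test_rescale_counts_simple(counts, expected):
    assert m.rescale_counts(*counts).as_tuple() == pytest.approx(expected)


def test_rescale_counts_sums_to_one():
    f = m.rescale_counts(88, 136, 3, 227)
    assert sum(f.as_tuple()) == pytest.approx(1.0, abs=1e-12)


def test_rescale_counts_errors():
    with pytest.raises(EstimationError):
        m.rescale_counts(0, 0, 0, 0)
    with pytest.raises(EstimationError):
        m.rescale_counts(1, 1, 1, 4)


def test_estimate_mu_true_arithmetic():
    assert m.estimate_mu(1) == pytest.approx(1 / 365)
    # true 8-year arithmetic is 1/2920, an order of magnitude below the
    # canonical constant carried by the source analysis
    assert m.estimate_mu(8) == pytest.approx(0.000342, abs=5e-7)
    assert m.MU_CANONICAL == 0.00342
    assert m.MU_TRUE_8_YEARS == pytest.approx(m.estimate_mu(8))
    with pytest.raises(EstimationError):
        m.estimate_mu(0)


def test_estimate_entry_probs_published_values():
    f = m.STUDY_INITIAL_FRACTIONS
    a, b, c = m.estimate_entry_probs(f, m.MU_CANONICAL)
    assert b == pytest.approx(0.4799, abs=1e-4)
    assert a == pytest.approx(0.3104, abs=2e-4)  # source prints 0.3104, true 0.3105
    assert c == pytest.approx(0.0105, abs=1e-4)


def test_estimate_entry_probs_zero_fraction():
    a, b, c = m.estimate_entry_probs(m.StateFractions(0, 0, 1), 0.01)
    assert a == 0 and b == 0
    with pytest.raises(EstimationError):
        m.estimate_entry_probs(m.StateFractions(0, 0, 1), 0)


@pytest.mark.parametrize(
    "contacts, needed, rate", [(5, 10, 0.5), (5, 25, 0.2), (0, 10, 0.0)]
)
def test_contact_rate(contacts, needed, rate):
    assert m.contact_rate(contacts, needed) == pytest.approx(rate)


def test_contact_rate_error():
    with pytest.raises(EstimationError):
        m.contact_rate(5, 0)


@pytest.mark.parametrize(
    "counts, weights, expected",
    [
        ((32, 13, 43), (1, 0.5, 0.15), 0.5108),  # high-vulnerability exercise
        ((60, 20, 56), (1, 0.5, 0.15), 0.5765),  # low-vulnerability exercise
        ((1, 0, 2), (2, 1, 0.3), 0.8667),  # complete-band technology
        ((63, 52, 21), (2, 1, 0.3), 1.3551),  # low-vulnerability technology
        ((5, 0, 0), (1, 0.5, 0.15), 1.0),
    ],
)
def test_weighted_mean_hours_published(counts, weights, expected):
    assert m.weighted_mean_hours(counts, weights) == pytest.approx(expected, abs=5e-5)


def test_weighted_mean_hours_errors():
    with pytest.raises(EstimationError):
        m.weighted_mean_hours((0, 0, 0), (1, 0.5, 0.15))


@given(
    counts=st.tuples(*[st.integers(0, 500)] * 3).filter(lambda c: sum(c) > 0),
    weights=st.tuples(*[st.floats(0, 10, allow_nan=False)] * 3),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_weighted_mean_bounded_by_weights(counts, weights):
    mean = m.weighted_mean_hours(counts, weights)
    assert min(weights) - 1e-12 <= mean <= max(weights) + 1e-12


@pytest.mark.parametrize(
    "h1, h2, days, expected, tol",
    [
        (0.5108, 0.5765, 30, 0.6796, 1e-4),  # exercise rate alpha
        (0.8666, 1.3551, 15, 0.6943, 1e-3),  # technology rate beta
        (1, 1, 24, 1.0, 1e-12),
    ],
)
def test_lifestyle_rate_published(h1, h2, days, expected, tol):
    assert m.lifestyle_rate(h1, h2, days) == pytest.approx(expected, abs=tol)


@given(
    h1=st.floats(0, 5, allow_nan=False),
    h2=st.floats(0, 5, allow_nan=False),
    scale=st.floats(0.1, 10, allow_nan=False),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_lifestyle_rate_linear_in_group_means(h1, h2, scale):
    base = m.lifestyle_rate(h1, h2, 30)
    assert m.lifestyle_rate(scale * h1, h2, 30) == pytest.approx(
        base + (scale - 1) * h1 * 30 / 48, abs=1e-9
    )
    assert m.lifestyle_rate(h1, scale * h2, 30) == pytest.approx(
        base + (scale - 1) * h2 * 30 / 48, abs=1e-9
    )


def test_lifestyle_rate_error():
    with pytest.raises(EstimationError):
        m.lifestyle_rate(1, 1, 0)


def test_estimate_all_reproduces_published_table(estimated):
    """Round-trip: reference cohort -> summary -> every published estimate."""
    p = estimated.params
    assert p.mu == 0.00342
    assert p.a == pytest.approx(0.3104, abs=2e-4)
    assert p.b == pytest.approx(0.4799, abs=2e-4)
    assert p.c == pytest.approx(0.0105, abs=1e-3)
    assert p.delta == 0.5
    assert p.epsilon == 0.2
    assert p.alpha == pytest.approx(0.6796, abs=1e-3)
    assert p.beta == pytest.approx(0.6941, abs=1e-3)
    assert estimated.hr == pytest.approx(0.5108, abs=5e-5)
    assert estimated.lr == pytest.approx(0.5765, abs=5e-5)
    assert estimated.cmh == pytest.approx(0.8667, abs=5e-5)
    assert estimated.lrt == pytest.approx(1.3551, abs=5e-5)


def test_estimate_all_chained_rounding(summary):
    """4-dp chained rounding reproduces the published chained arithmetic."""
    rep = m.estimate_all(summary, m.EstimationConfig(chained_rounding=True))
    assert round(rep.params.b, 4) == 0.4799
    assert round(rep.params.alpha, 4) == 0.6796
    assert round(rep.params.beta, 4) == 0.6943


def test_estimate_all_missing_band_errors(summary):
    broken = m.CohortSummary(
        n_total=summary.n_total,
        band_counts=dict(summary.band_counts),
        exercise_counts=dict(summary.exercise_counts),
        tech_counts={**summary.tech_counts, "complete": (0, 0, 0)},
        sex_counts=dict(summary.sex_counts),
    )
    with pytest.raises(EstimationError, match="beta"):
        m.estimate_all(broken)


def test_estimate_all_respects_overrides(summary):
    rep = m.estimate_all(summary, m.EstimationConfig(delta=0.9, epsilon=0.05))
    assert rep.params.delta == 0.9
    assert rep.params.epsilon == 0.05


def test_model_parameters_validation():
    with pytest.raises(ValueError):
        m.STUDY_PARAMETERS.replace(a=1.2)
    with pytest.raises(ValueError):
        m.STUDY_PARAMETERS.replace(mu=-0.1)
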