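"""Equilibrium cubic, Vieta screening and disease-free-equilibrium stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mddvuln as m
from mddvuln.equilibrium import DegenerateCubicError, SingularDenominatorError

positive_rates = st.floats(1e-3, 3.0, allow_nan=False)
probs = st.floats(0.0, 1.0, allow_nan=False)


def _params(mu, a, b, c, delta, epsilon, alpha, beta):
    return m.ModelParameters(mu=mu, a=a, b=b, c=c, delta=delta,
                             epsilon=epsilon, alpha=alpha, beta=beta)


def _coefficients_oracle(p):
    """Independent re-evaluation: each printed monomial summed separately."""
    mu, a, c = p.mu, p.a, p.c
    d, e, al, be = p.delta, p.epsilon, p.alpha, p.beta
    A = sum([e * d])
    B = -sum([mu * d, e * d, e * be, al * d, mu * e])
    C = sum([mu * d, -a * mu * d, mu * mu, mu * be, e * mu, e * be,
             al * d, al * mu, al * be, -c * e * mu])
    D = sum([a * mu * mu, a * mu * be, -mu * mu, -mu * be, -al * mu,
             -al * be, c * mu * mu, c * mu * al])
    return (A, B, C, D)


def test_cubic_coefficients_simple():
    p = _params(0, 0, 0, 0, delta=0.5, epsilon=0.2, alpha=0, beta=0)
    coeffs = m.cubic_coefficients(p)
    assert coeffs.A == pytest.approx(0.1)
    p0 = _params(0, 0, 0, 0, 0, 0, 0, 0)
    assert m.cubic_coefficients(p0).as_tuple() == (0, 0, 0, 0)


def test_cubic_coefficients_against_term_oracle(study_params):
    coeffs = m.cubic_coefficients(study_params)
    oracle = _coefficients_oracle(study_params)
    assert coeffs.as_tuple() == pytest.approx(oracle, abs=1e-12)


def test_cubic_coefficients_oracle_random():
    rng = np.random.default_rng(3)
    for _ in range(50):
        p = _params(*rng.uniform(0.01, 1, size=4), *rng.uniform(0.01, 2, size=4))
        assert m.cubic_coefficients(p).as_tuple() == pytest.approx(
            _coefficients_oracle(p), abs=1e-12
        )


def test_vieta_known_factorization():
    # (y-1)(y-2)(y-3) = y^3 - 6y^2 + 11y - 6
    v = m.vieta(m.CubicCoefficients(1, -6, 11, -6))
    assert (v.S1, v.S2, v.P) == pytest.approx((6, 11, 6))
    v0 = m.vieta(m.CubicCoefficients(1, 0, 0, 0))
    assert (v0.S1, v0.S2, v0.P) == (0, 0, 0)


def test_vieta_degenerate():
    with pytest.raises(DegenerateCubicError):
        m.vieta(m.CubicCoefficients(0, 1, 1, 1))


def test_vieta_matches_symmetric_functions_of_roots(study_params):
    coeffs = m.cubic_coefficients(study_params)
    v = m.vieta(coeffs)
    roots = np.roots(coeffs.as_tuple())
    s1 = roots.sum()
    s2 = roots[0] * roots[1] + roots[0] * roots[2] + roots[1] * roots[2]
    prod = roots.prod()
    assert v.S1 == pytest.approx(float(s1.real), abs=1e-8)
    assert v.S2 == pytest.approx(float(s2.real), abs=1e-8)
    assert v.P == pytest.approx(float(prod.real), abs=1e-8)


def test_positivity_conditions_study(study_params):
    s1_pos, s2_pos, p_pos = m.positivity_conditions(study_params)
    assert s1_pos  # every summand of mu*d + e*d + e*be + al*d + mu*e positive


def test_positivity_matches_vieta_signs():
    rng = np.random.default_rng(17)
    for _ in range(100):
        p = _params(*rng.uniform(0.01, 1, size=4), *rng.uniform(0.01, 2, size=4))
        v = m.vieta(m.cubic_coefficients(p))
        assert m.positivity_conditions(p) == (v.S1 > 0, v.S2 > 0, v.P > 0)


def test_positivity_degenerate():
    p = _params(0.1, 0.3, 0.5, 0.2, delta=0, epsilon=1, alpha=0.1, beta=0.1)
    with pytest.raises(DegenerateCubicError):
        m.positivity_conditions(p)


def test_solve_known_cubic_roots():
    # solve the factored cubic through a parameter set is impossible, so use
    # the low-level path: residuals of the companion-matrix roots
    roots = np.roots([1, -6, 11, -6])
    assert sorted(roots.real) == pytest.approx([1, 2, 3])


def test_solve_equilibrium_roots_residuals(study_params):
    coeffs = m.cubic_coefficients(study_params)
    roots = m.solve_equilibrium_y(study_params)
    assert roots == sorted(roots, key=lambda r: r.y)
    scale = max(1.0, *(abs(c) for c in coeffs.as_tuple()))
    for r in roots:
        assert abs(r.residual) < 1e-9 * scale
        assert r.admissible == (0 <= r.y <= 1)


def test_solve_equilibrium_admissible_upper(study_params):
    abc = study_params.a + study_params.b + study_params.c
    roots_unit = m.solve_equilibrium_y(study_params)
    roots_abc = m.solve_equilibrium_y(study_params, admissible_upper=abc)
    assert [r.y for r in roots_unit] == [r.y for r in roots_abc]


def test_equilibrium_root_matches_integrator(study_params):
    """Normalized entry: smallest admissible root == terminal y of a long run."""
    pn = m.normalized_entry(study_params)
    traj = m.integrate(pn, m.STUDY_INITIAL_FRACTIONS)
    admissible = [r.y for r in m.solve_equilibrium_y(pn) if r.admissible]
    assert admissible
    assert min(admissible) == pytest.approx(traj.terminal[1], abs=1e-5)


def test_equilibrium_z_cases(study_params):
    p = study_params
    # hand substitution at y = 0.5: c*mu / (beta + mu - delta/2)
    expected = p.c * p.mu / (0.6941 + 0.00342 - 0.25)
    assert m.equilibrium_z(0.5, p) == pytest.approx(expected, abs=1e-12)
    assert m.equilibrium_z(0.3, p.replace(c=0)) == 0.0
    p_dec = p.replace(delta=0)
    assert m.equilibrium_z(0.7, p_dec) == pytest.approx(
        p.c * p.mu / (p.beta + p.mu)
    )


def test_equilibrium_z_singular(study_params):
    p = study_params
    y_sing = (p.beta + p.mu) / p.delta
    with pytest.raises(SingularDenominatorError):
        m.equilibrium_z(y_sing, p)


def test_jacobian_dfe_structure(study_params):
    p = study_params
    J = m.jacobian_dfe(p)
    assert J[0, 0] == pytest.approx(-(0.00342 + 0.6796))
    assert J[0, 1] == 0 and J[0, 2] == 0 and J[2, 0] == 0
    assert m.jacobian_dfe(_params(0, 0, 0, 0, 0, 0, 0, 0)) == pytest.approx(
        np.zeros((3, 3))
    )


def test_jacobian_matches_finite_differences(study_params):
    """Analytic DFE Jacobian equals numerical differentiation of the field."""
    p = study_params
    J = m.jacobian_dfe(p)
    s0 = np.array([0.0, 0.0, 1.0])
    h = 1e-6
    num = np.zeros((3, 3))
    for j in range(3):
        sp, sm = s0.copy(), s0.copy()
        sp[j] += h
        sm[j] -= h
        num[:, j] = (
            np.array(m.derivatives(sp, p)) - np.array(m.derivatives(sm, p))
        ) / (2 * h)
    assert np.max(np.abs(J - num)) < 1e-5


def test_closed_form_eigenvalues_match_numeric_1000_draws():
    """Closed forms -(mu+alpha), -mu, -(mu+beta+delta) across random draws."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        p = _params(*rng.uniform(0, 1, size=4), *rng.uniform(0, 2, size=4))
        closed = np.sort(m.closed_form_eigenvalues(p))
        numeric = np.sort(np.linalg.eigvals(m.jacobian_dfe(p)).real)
        assert np.max(np.abs(closed - numeric)) < 1e-10


@given(mu=positive_rates, a=probs, b=probs, c=probs,
       delta=positive_rates, epsilon=positive_rates,
       alpha=positive_rates, beta=positive_rates)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_stable_for_strictly_positive_parameters(mu, a, b, c, delta, epsilon,
                                                 alpha, beta):
    p = _params(mu, a, b, c, delta, epsilon, alpha, beta)
    report = m.stability_analysis(p)
    assert report.stable
    assert all(ev < 0 for ev in report.eigenvalues)


def test_stability_report_study(study_params):
    rep = m.stability_analysis(study_params)
    assert rep.eigenvalues[1] == pytest.approx(-0.00342)
    assert rep.stable
    assert rep.r0_literal == pytest.approx(-0.00342 + 0.6941 + 0.5)
    assert rep.r0_bound == pytest.approx(0.5 * (0.00342 + 0.6796) / 0.2)
    # the report must flag that r0_literal > 1 coexists with stability
    assert rep.r0_literal > 1
    assert any("inconsisten" in n for n in rep.notes)


def test_stability_zero_epsilon():
    p = _params(1, 0, 0, 0, delta=0, epsilon=0, alpha=0, beta=0)
    rep = m.stability_analysis(p)
    assert rep.eigenvalues == (-1, -1, -1)
    assert rep.stable
    assert rep.r0_bound is None
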