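"""Liability-threshold study simulator: determinism, model structure and
agreement with closed-form expectations."""

import math
from itertools import product

import numpy as np
import pytest
from scipy.stats import norm

from famline.roster_model import Group, RelativeClass
from famline.aggregation import prevalence_by_stratum
from famline.synthetic_data import (
    DEFAULT_STRUCTURE,
    RelativeModel,
    SimulationConfig,
    expected_relative_prevalence,
    family_relatedness_matrix,
    simulate_sibships,
    simulate_study,
)

FIRST_DEGREE_ONLY = {
    RelativeClass.parent: 2,
    RelativeClass.sibling: 2,
    RelativeClass.offspring: 1,
}


def _arm_prevalence(roster, group):
    cell = prevalence_by_stratum(roster, "all", with_tests=False).cell(group, "all")
    return float(cell.q), cell.n_total


# ---------------------------------------------------------------------------
# determinism and contract


def test_fixed_seed_reproduces_roster_exactly():
    cfg = SimulationConfig(n_case_families=30, n_control_families=30, seed=11)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    assert a.roster == b.roster
    assert a.sibships == b.sibships
    c = simulate_study(SimulationConfig(n_case_families=30,
                                        n_control_families=30, seed=12))
    assert c.roster != a.roster


def test_proband_status_and_sibship_derivation():
    cfg = SimulationConfig(n_case_families=50, n_control_families=50, seed=3)
    study = simulate_study(cfg)
    # sibships come from the case arm: proband + 2 siblings per household
    assert study.sibships.households == 50
    assert study.sibships.T == 50 * 3
    # every household counts its affected proband, so R >= households
    assert study.sibships.R >= 50
    case_sibs = [
        r for r in study.roster
        if r.group == Group.case and r.relative_class == RelativeClass.sibling
    ]
    assert study.sibships.R == 50 + sum(r.affected for r in case_sibs)


def test_default_structure_matches_surveyed_family_sizes():
    counts = {1: 0, 2: 0, 3: 0}
    for cls, k in DEFAULT_STRUCTURE.items():
        counts[cls.degree] += k
    assert counts == {1: 5, 2: 4, 3: 3}


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(K=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(h2_true=1.5)


# ---------------------------------------------------------------------------
# pedigree relatedness (full-MVN model)


def test_relatedness_matrix_against_classical_coefficients():
    r_mat, classes = family_relatedness_matrix(DEFAULT_STRUCTURE)
    assert r_mat.shape == (13, 13)
    np.testing.assert_allclose(r_mat, r_mat.T)
    np.testing.assert_allclose(np.diag(r_mat), 1.0)
    for i, cls in enumerate(classes, start=1):
        assert r_mat[0, i] == pytest.approx(float(cls.relatedness_r)), cls
    # the liability correlation matrix must be positive semi-definite
    eig = np.linalg.eigvalsh(r_mat * 0.8 + np.eye(13) * 0.2)
    assert eig.min() > -1e-10
    # siblings are related 1/2 to each other, parents (mates) unrelated
    sib = [i + 1 for i, c in enumerate(classes) if c == RelativeClass.sibling]
    par = [i + 1 for i, c in enumerate(classes) if c == RelativeClass.parent]
    assert r_mat[sib[0], sib[1]] == pytest.approx(0.5)
    assert r_mat[par[0], par[1]] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# independence limit and arm/degree ordering


def test_zero_heritability_prevalence_matches_population():
    n = 2000  # 10k first-degree relatives per arm
    cfg = SimulationConfig(h2_true=0.0, n_case_families=n, n_control_families=n,
                           structure=FIRST_DEGREE_ONLY, seed=7)
    study = simulate_study(cfg)
    for group in Group:
        q, m = _arm_prevalence(
            [r for r in study.roster if r.group == group], group
        )
        mc_se = math.sqrt(cfg.K * (1 - cfg.K) / m)
        assert abs(q - cfg.K) < 3 * mc_se


def test_arm_and_degree_ordering():
    cfg = SimulationConfig(h2_true=0.8, n_case_families=3000,
                           n_control_families=3000, seed=5)
    study = simulate_study(cfg)
    table = prevalence_by_stratum(study.roster, "degree", with_tests=False)
    case_q = [float(table.cell(Group.case, d).q) for d in (1, 2, 3)]
    ctrl_q = [float(table.cell(Group.control, d).q) for d in (1, 2, 3)]
    assert case_q[0] > case_q[1] > case_q[2]
    assert all(c > k for c, k in zip(case_q, ctrl_q))


# ---------------------------------------------------------------------------
# closed-form companion


def test_expected_prevalence_zero_heritability_is_population():
    for arm in ("case", "control"):
        assert expected_relative_prevalence(0.2322, 0.0, 0.5, arm) == 0.2322


def test_expected_prevalence_monotone_in_relatedness():
    qs = [
        expected_relative_prevalence(0.2322, 0.6, r, "case")
        for r in (0.125, 0.25, 0.5)
    ]
    assert qs[0] < qs[1] < qs[2]
    # and the control arm moves the other way, below the population value
    qc = [
        expected_relative_prevalence(0.2322, 0.6, r, "control")
        for r in (0.125, 0.25, 0.5)
    ]
    assert qc[0] > qc[1] > qc[2]
    assert all(q < 0.2322 for q in qc)


def test_quadrature_agrees_with_closed_form_at_full_correlation():
    """With rho = 1, a parent shares the proband's liability exactly."""
    K = 0.3
    q = expected_relative_prevalence(K, 1.0, 1.0, "case")
    assert q == pytest.approx(1.0, abs=1e-8)
    q0 = expected_relative_prevalence(K, 1.0, 1.0, "control")
    assert q0 == pytest.approx(0.0, abs=1e-8)


def test_simulator_matches_quadrature():
    """Empirical case/control first-degree prevalence vs 1-D integration."""
    K, h2 = 0.2322, 0.5
    n = 6000
    cfg = SimulationConfig(K=K, h2_true=h2, n_case_families=n,
                           n_control_families=n,
                           structure=FIRST_DEGREE_ONLY, seed=29)
    study = simulate_study(cfg)
    for group in Group:
        q_hat, m = _arm_prevalence(
            [r for r in study.roster if r.group == group], group
        )
        q_exp = expected_relative_prevalence(K, h2, 0.5, group.value)
        mc_se = math.sqrt(q_exp * (1 - q_exp) / m)
        assert abs(q_hat - q_exp) < 4 * mc_se, (group, q_hat, q_exp)


def test_full_mvn_marginal_matches_quadrature():
    """Joint family draws keep each relative's marginal rho = r h2."""
    K, h2 = 0.2322, 0.6
    cfg = SimulationConfig(K=K, h2_true=h2, n_case_families=4000,
                           n_control_families=0,
                           relative_model=RelativeModel.full_mvn, seed=17)
    study = simulate_study(cfg)
    table = prevalence_by_stratum(study.roster, "degree", with_tests=False)
    for degree, r in ((1, 0.5), (2, 0.25), (3, 0.125)):
        cell = table.cell(Group.case, degree)
        q_exp = expected_relative_prevalence(K, h2, r, "case")
        mc_se = math.sqrt(q_exp * (1 - q_exp) / cell.n_total)
        assert abs(float(cell.q) - q_exp) < 4 * mc_se, degree


# ---------------------------------------------------------------------------
# sibship simulation and ascertainment


def _enumerate_single_ascertainment(size, theta):
    """Exact per-ascertained-sibship expectations under single selection.

    Affection is i.i.d. Bernoulli(theta) (the h2 = 0 case); a sibship is
    selected with probability proportional to its affected count k.
    Returns expected (R, J, Q) per selected sibship.
    """
    weights, stats = [], []
    for k in range(1, size + 1):
        pk = math.comb(size, k) * theta**k * (1 - theta) ** (size - k)
        weights.append(k * pk)
        stats.append((k, int(k == 1), int(k == 2)))
    z = sum(weights)
    er = sum(w * s[0] for w, s in zip(weights, stats)) / z
    ej = sum(w * s[1] for w, s in zip(weights, stats)) / z
    eq = sum(w * s[2] for w, s in zip(weights, stats)) / z
    return er, ej, eq


@pytest.mark.parametrize("size", [2, 3])
def test_single_ascertainment_matches_enumeration(size):
    K = 0.3
    cfg = SimulationConfig(K=K, h2_true=0.0, seed=41)
    n = 40_000
    table = simulate_sibships(cfg, "single", n_sibships=n, sibship_size=size)
    m = table.households
    er, ej, eq = _enumerate_single_ascertainment(size, K)
    # per-household empirical means vs enumeration, binomial-scale MC error
    assert table.R / m == pytest.approx(er, abs=4 * math.sqrt(size / m))
    assert table.J / m == pytest.approx(ej, abs=4 * math.sqrt(ej * (1 - ej) / m))
    assert table.Q / m == pytest.approx(eq, abs=4 * math.sqrt(max(eq, 0.01) / m))


def test_complete_ascertainment_includes_every_affected_sibship():
    cfg = SimulationConfig(K=0.4, h2_true=0.0, seed=19)
    n = 20_000
    table = simulate_sibships(cfg, "complete", pi=1.0, n_sibships=n,
                              sibship_size=2)
    # expected fraction of sibships with >= 1 affected: 1 - (1-K)^2
    frac = table.households / n
    expect = 1 - 0.6**2
    assert frac == pytest.approx(expect, abs=4 * math.sqrt(expect / n))
    # J counts exactly the single-case households among those
    p1 = 2 * 0.4 * 0.6 / expect
    assert table.J / table.households == pytest.approx(
        p1, abs=4 * math.sqrt(p1 / table.households)
    )


def test_size_one_sibships_force_degenerate_estimator():
    from famline.weinberg import segregation_ratio

    cfg = SimulationConfig(K=0.3, h2_true=0.0, seed=23)
    table = simulate_sibships(cfg, "single", n_sibships=2000, sibship_size=1)
    assert table.R == table.J  # every ascertained household is its proband
    with pytest.raises(ZeroDivisionError):
        segregation_ratio(table)


def test_sibship_rejects_bad_ascertainment():
    cfg = SimulationConfig(seed=1)
    with pytest.raises(ValueError):
        simulate_sibships(cfg, "single", pi=0.0)
    with pytest.raises(ValueError):
        simulate_sibships(cfg, "census")  # type: ignore[arg-type]
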