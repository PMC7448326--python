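"""Kappa-family estimators against hand values and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.stats.inter_rater as smir

from equipoise import (
    bootstrap_ci,
    cohen_kappa,
    fleiss_kappa,
    interpret_kappa,
    pabak,
    percent_agreement,
    subgroup_agreement,
    validate_matrix,
)
from equipoise.agreement import fleiss_from_counts
from equipoise.decision_data import DecisionRecord, RaterProfile
from equipoise.errors import (
    DegenerateChanceError,
    InsufficientCasesError,
    ValidationError,
)

from conftest import matrix_from_counts, random_matrix
from oracles import cohen_kappa_oracle, fleiss_kappa_oracle, scott_pi_oracle


# ---------------------------------------------------------------------------
# percent agreement


def test_percent_agreement_perfect():
    m = matrix_from_counts([3, 0, 3], n_raters=3)
    assert percent_agreement(m, "q1").kappa == pytest.approx(1.0)


def test_percent_agreement_total_disagreement_two_raters():
    m = matrix_from_counts([1, 1, 1], n_raters=2)
    assert percent_agreement(m, "q1").kappa == pytest.approx(0.0)


def test_percent_agreement_hand_value():
    # 3 raters, 5 binary cases, yes-counts (3,3,0,2,1): mean P_i = 11/15
    m = matrix_from_counts([3, 3, 0, 2, 1], n_raters=3)
    assert percent_agreement(m, "q1").kappa == pytest.approx(0.73333, abs=1e-4)


# ---------------------------------------------------------------------------
# Fleiss


def test_fleiss_perfect_agreement_both_categories():
    m = matrix_from_counts([3, 0, 3, 0], n_raters=3)
    res = fleiss_kappa(m, "q1")
    assert res.kappa == pytest.approx(1.0)
    assert res.band == "almost perfect"


def test_fleiss_systematic_split_is_minus_one():
    m = matrix_from_counts([1, 1, 1, 1], n_raters=2)
    res = fleiss_kappa(m, "q1")
    assert res.kappa == pytest.approx(-1.0)
    assert res.observed_agreement == pytest.approx(0.0)
    assert res.chance_agreement == pytest.approx(0.5)


def test_fleiss_hand_value():
    m = matrix_from_counts([3, 3, 0, 2, 1], n_raters=3)
    res = fleiss_kappa(m, "q1")
    assert res.observed_agreement == pytest.approx(0.73333, abs=1e-4)
    assert res.chance_agreement == pytest.approx(0.52)
    assert res.kappa == pytest.approx(0.44444, abs=1e-4)


def test_fleiss_degenerate_single_category():
    m = matrix_from_counts([3, 3], n_raters=3)
    with pytest.raises(DegenerateChanceError):
        fleiss_kappa(m, "q1")


def test_fleiss_insufficient_cases():
    with pytest.raises(InsufficientCasesError):
        fleiss_from_counts(np.array([[2.0, 1.0]]))


def test_fleiss_internal_identity(rng):
    """kappa == (P_bar - P_e) / (1 - P_e) and sum p_j == 1."""
    m = random_matrix(rng)
    res = fleiss_kappa(m, "q1")
    assert res.kappa == pytest.approx(
        (res.observed_agreement - res.chance_agreement) / (1 - res.chance_agreement),
        abs=1e-12,
    )
    assert sum(res.category_proportions.values()) == pytest.approx(1.0, abs=1e-12)


def test_fleiss_matches_bruteforce_oracle_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(60):
        m = random_matrix(rng)
        tab = m.count_table("q1")
        try:
            res = fleiss_kappa(m, "q1")
        except DegenerateChanceError:
            continue
        assert res.kappa == pytest.approx(
            fleiss_kappa_oracle(tab.values.tolist()), abs=1e-10
        )


def test_fleiss_matches_statsmodels_equal_n(rng):
    m = random_matrix(rng, n_raters=5, n_cases=12, n_categories=3)
    tab = m.count_table("q1").to_numpy()
    assert fleiss_kappa(m, "q1").kappa == pytest.approx(
        smir.fleiss_kappa(tab), abs=1e-10
    )


def test_fleiss_unequal_raters_per_case():
    """Missing responses: excluded cases counted, pooled p_j weighted by
    assignments."""
    recs = [
        DecisionRecord("r1", "c1", 1, "q1", "yes"),
        DecisionRecord("r2", "c1", 1, "q1", "yes"),
        DecisionRecord("r3", "c1", 1, "q1", "no"),
        DecisionRecord("r1", "c2", 1, "q1", "no"),
        DecisionRecord("r2", "c2", 1, "q1", "no"),
        DecisionRecord("r1", "c3", 1, "q1", "yes"),  # single rater: excluded
    ]
    m = validate_matrix(recs)
    res = fleiss_kappa(m, "q1")
    assert res.n_cases == 2
    assert res.n_excluded_cases == 1
    assert res.kappa == pytest.approx(
        fleiss_kappa_oracle([[1, 2], [2, 0]]), abs=1e-12
    )


def test_two_rater_fleiss_equals_scott_pi(rng):
    """With 2 raters and complete data Fleiss' kappa is Scott's pi."""
    for _ in range(20):
        m = random_matrix(rng, n_raters=2, n_cases=10)
        sl = m.slice("q1", 1).pivot(index="case_id", columns="rater_id", values="choice")
        try:
            res = fleiss_kappa(m, "q1")
        except DegenerateChanceError:
            continue
        pi = scott_pi_oracle(sl.iloc[:, 0], sl.iloc[:, 1], m.categories)
        assert res.kappa == pytest.approx(pi, abs=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_label_permutation_invariance(seed):
    """Relabeling categories leaves fleiss/cohen/pabak unchanged."""
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, n_raters=3, n_cases=6, n_categories=2)
    swap = {"opt0": "opt1", "opt1": "opt0"}
    df = m.data.copy()
    df["choice"] = df["choice"].map(swap)
    m2 = validate_matrix(df, categories=m.categories)
    try:
        k1 = fleiss_kappa(m, "q1").kappa
        k2 = fleiss_kappa(m2, "q1").kappa
    except DegenerateChanceError:
        return
    assert k1 == pytest.approx(k2, abs=1e-12)
    try:
        c1 = cohen_kappa(m, "q1", "r0", "r1").kappa
        c2 = cohen_kappa(m2, "q1", "r0", "r1").kappa
        assert c1 == pytest.approx(c2, abs=1e-12)
    except DegenerateChanceError:
        pass
    assert pabak(m, "q1", "r0", "r1").kappa == pytest.approx(
        pabak(m2, "q1", "r0", "r1").kappa, abs=1e-12
    )


def test_adding_unanimous_case_never_decreases_observed_agreement(rng):
    for _ in range(10):
        yes = list(rng.integers(0, 4, size=5))
        base = matrix_from_counts(yes, n_raters=3)
        extended = matrix_from_counts(yes + [3], n_raters=3)
        assert (
            percent_agreement(extended, "q1").kappa
            >= percent_agreement(base, "q1").kappa - 1e-12
        )


# ---------------------------------------------------------------------------
# Cohen / PABAK


def _two_rater_matrix(table):
    """table[(i,j)] cases where rater a chose cat i and rater b chose cat j."""
    recs = []
    c = 0
    for (ca, cb), n in table.items():
        for _ in range(n):
            recs.append(DecisionRecord("a", f"c{c}", 1, "q1", ca))
            recs.append(DecisionRecord("b", f"c{c}", 1, "q1", cb))
            c += 1
    return validate_matrix(recs, categories=("no", "yes"))


def test_cohen_identical_raters():
    m = _two_rater_matrix({("yes", "yes"): 6, ("no", "no"): 4})
    assert cohen_kappa(m, "q1", "a", "b").kappa == pytest.approx(1.0)


def test_cohen_one_constant_rater_is_zero():
    m = _two_rater_matrix({("yes", "yes"): 6, ("no", "yes"): 4})
    assert cohen_kappa(m, "q1", "a", "b").kappa == pytest.approx(0.0, abs=1e-12)


def test_cohen_hand_value_2x2():
    # cross-table (20, 5; 10, 15) over 50 cases: p_o=0.7, p_e=0.5, kappa=0.4
    m = _two_rater_matrix(
        {("yes", "yes"): 20, ("yes", "no"): 5, ("no", "yes"): 10, ("no", "no"): 15}
    )
    res = cohen_kappa(m, "q1", "a", "b")
    assert res.observed_agreement == pytest.approx(0.7)
    assert res.chance_agreement == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.4)


def test_cohen_matches_statsmodels(rng):
    for _ in range(10):
        m = random_matrix(rng, n_raters=2, n_cases=12, n_categories=3)
        sl = m.slice("q1", 1).pivot(index="case_id", columns="rater_id", values="choice")
        a, b = sl.iloc[:, 0], sl.iloc[:, 1]
        try:
            ours = cohen_kappa(m, "q1", "r0", "r1").kappa
        except DegenerateChanceError:
            continue
        import pandas as pd

        tab = pd.crosstab(
            pd.Categorical(a, m.categories), pd.Categorical(b, m.categories),
            dropna=False,
        ).to_numpy()
        assert ours == pytest.approx(smir.cohens_kappa(tab).kappa, abs=1e-10)
        assert ours == pytest.approx(cohen_kappa_oracle(a, b, m.categories), abs=1e-12)


def test_cohen_no_shared_cases():
    recs = [
        DecisionRecord("a", "c1", 1, "q1", "yes"),
        DecisionRecord("b", "c2", 1, "q1", "no"),
    ]
    m = validate_matrix(recs)
    with pytest.raises(InsufficientCasesError):
        cohen_kappa(m, "q1", "a", "b")


def test_pabak_values():
    m = _two_rater_matrix(
        {("yes", "yes"): 20, ("yes", "no"): 5, ("no", "yes"): 10, ("no", "no"): 15}
    )
    assert pabak(m, "q1", "a", "b").kappa == pytest.approx(0.4)
    perfect = _two_rater_matrix({("yes", "yes"): 5, ("no", "no"): 5})
    assert pabak(perfect, "q1", "a", "b").kappa == pytest.approx(1.0)
    chance = _two_rater_matrix(
        {("yes", "yes"): 3, ("yes", "no"): 3, ("no", "yes"): 2, ("no", "no"): 2}
    )
    assert pabak(chance, "q1", "a", "b").kappa == pytest.approx(0.0)


def test_pabak_requires_binary():
    rng = np.random.default_rng(0)
    m = random_matrix(rng, n_raters=2, n_cases=6, n_categories=3)
    with pytest.raises(ValidationError):
        pabak(m, "q1", "r0", "r1")


def test_pabak_dominates_cohen_under_same_direction_imbalance(rng):
    """When both raters' marginals lean the same way, chance agreement
    exceeds 1/2, so PABAK >= Cohen's kappa."""
    for _ in range(30):
        # both raters vote yes on > half the cases
        n = 20
        a_yes = int(rng.integers(11, n))
        b_yes = int(rng.integers(11, n))
        a = ["yes"] * a_yes + ["no"] * (n - a_yes)
        b = ["yes"] * b_yes + ["no"] * (n - b_yes)
        rng.shuffle(b)
        recs = []
        for i in range(n):
            recs.append(DecisionRecord("a", f"c{i}", 1, "q1", a[i]))
            recs.append(DecisionRecord("b", f"c{i}", 1, "q1", b[i]))
        m = validate_matrix(recs, categories=("no", "yes"))
        try:
            ck = cohen_kappa(m, "q1", "a", "b").kappa
        except DegenerateChanceError:
            continue
        assert pabak(m, "q1", "a", "b").kappa >= ck - 1e-12


# ---------------------------------------------------------------------------
# interpretation bands


@pytest.mark.parametrize(
    "kappa,band,below",
    [
        (-0.3, "poor", True),
        (0.0, "slight", True),
        (0.20, "slight", True),
        (0.35, "fair", True),
        (0.55, "moderate", True),
        (0.60, "moderate", True),
        (0.75, "substantial", False),
        (0.80, "substantial", False),
        (0.95, "almost perfect", False),
        (1.0, "almost perfect", False),
    ],
)
def test_landis_koch_bands(kappa, band, below):
    res = interpret_kappa(kappa)
    assert res.band == band
    assert res.below_substantial is below


def test_interpret_rejects_kappa_above_one():
    with pytest.raises(ValidationError):
        interpret_kappa(1.2)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_perfect_agreement_degenerate_interval():
    m = matrix_from_counts([3, 0, 3, 0], n_raters=3)
    res = bootstrap_ci(m, "q1", B=200, seed=1)
    assert res.ci_lower == pytest.approx(1.0)
    assert res.ci_upper == pytest.approx(1.0)


def test_bootstrap_seeded_determinism():
    m = matrix_from_counts([3, 3, 0, 2, 1, 2, 1, 0], n_raters=3)
    r1 = bootstrap_ci(m, "q1", B=500, seed=42)
    r2 = bootstrap_ci(m, "q1", B=500, seed=42)
    assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)


def test_bootstrap_interval_contains_estimate_and_stable_width():
    from equipoise.simulate_design import SimulationConfig, simulate_decisions

    m = simulate_decisions(SimulationConfig(n_raters=10, n_cases=40, seed=11))
    r1 = bootstrap_ci(m, "decision", B=1000, seed=1)
    r2 = bootstrap_ci(m, "decision", B=1000, seed=2)
    assert r1.ci_lower <= r1.kappa <= r1.ci_upper
    assert r1.ci_upper > r1.ci_lower
    w1, w2 = r1.ci_upper - r1.ci_lower, r2.ci_upper - r2.ci_lower
    assert abs(w1 - w2) / w1 < 0.2


def test_bootstrap_b_too_small():
    m = matrix_from_counts([3, 1], n_raters=3)
    with pytest.raises(ValidationError):
        bootstrap_ci(m, "q1", B=50)


def test_bootstrap_percent_method():
    m = matrix_from_counts([3, 3, 0, 2, 1], n_raters=3)
    res = bootstrap_ci(m, "q1", method="percent", B=200, seed=0)
    assert res.method == "percent"
    assert res.ci_lower <= res.kappa <= res.ci_upper


# ---------------------------------------------------------------------------
# subgroups


def _roster(mapping):
    return [RaterProfile(rater_id=r, specialty=s) for r, s in mapping.items()]


def test_subgroup_trivial_partition_equals_global(rng):
    m = random_matrix(rng, n_raters=4, n_cases=8, n_categories=2)
    roster = _roster({f"r{i}": "one" for i in range(4)})
    results = subgroup_agreement(m, roster, None, "q1", by="specialty")
    assert len(results) == 1
    assert results[0].kappa == pytest.approx(fleiss_kappa(m, "q1").kappa, abs=1e-12)


def test_subgroup_by_specialty_on_fixture(fixture_study):
    matrix, portfolio, roster = fixture_study
    results = subgroup_agreement(matrix, roster, None, "thrombectomy", by="specialty")
    labels = {r.subgroup for r in results}
    assert labels == {"specialty=neurology", "specialty=interventional"}
    for r in results:
        assert r.status == "ok"
        assert r.kappa < 0.6


def test_subgroup_small_case_partition_flagged(fixture_study):
    matrix, portfolio, roster = fixture_study
    results = subgroup_agreement(
        matrix, None, portfolio, "thrombectomy", by="control_class"
    )
    by_label = {r.subgroup: r for r in results}
    assert set(by_label) == {
        "control_class=positive", "control_class=grey", "control_class=negative"
    }
    # 13-14 cases per class: well below the 30-case rule of thumb
    assert all(r.caution_wide_ci for r in results if r.status == "ok")
    # full-portfolio specialty subgroups (41 cases) are not flagged
    by_spec = subgroup_agreement(matrix, roster, None, "thrombectomy", by="specialty")
    assert all(not r.caution_wide_ci for r in by_spec if r.status == "ok")


def test_subgroup_insufficient_marker():
    m = matrix_from_counts([3, 0, 2], n_raters=3)
    roster = _roster({"r1": "a", "r2": "a", "r3": "b"})
    results = subgroup_agreement(m, roster, None, "q1", by="specialty")
    by_label = {r.subgroup: r for r in results}
    # subgroup b has a single rater everywhere: no case reaches n_i >= 2
    assert by_label["specialty=b"].status == "insufficient"
    assert by_label["specialty=a"].status == "ok"


def test_subgroup_unknown_field():
    m = matrix_from_counts([2, 1], n_raters=3)
    with pytest.raises(ValidationError):
        subgroup_agreement(m, None, None, "q1", by="starsign")
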