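"""Unit and oracle tests for the diplotype HMM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsqtl.hmm import (
    MISSING,
    DiplotypeProbs,
    FounderPanel,
    diplotype_states,
    dosages_from_probs,
    emission_probability,
    forward_backward,
    snp_dosage,
    transition_matrix,
    _haplotype_kernel,
)


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "F, n_states, n_het",
    [(8, 36, 28), (2, 3, 1), (3, 6, 3)],
)
def test_state_counts(F, n_states, n_het):
    states, het = diplotype_states(F)
    assert len(states) == n_states
    assert int(het.sum()) == n_het
    # canonical order is stable and matches unordered-pair enumeration
    assert states == [(i, j) for i in range(F) for j in range(i, F)]


def test_states_f3_enumeration_oracle():
    # brute-force: all unordered pairs of 3 founders
    expected = sorted({tuple(sorted(p)) for p in itertools.product(range(3), repeat=2)})
    states, het = diplotype_states(3)
    assert sorted(states) == expected
    assert [h for h in het] == [i != j for i, j in states]


def test_states_rejects_f1():
    with pytest.raises(ValueError):
        diplotype_states(1)


# ---------------------------------------------------------------------------
# Transition matrix
# ---------------------------------------------------------------------------


def test_transition_zero_distance_identity():
    T = transition_matrix(0.0, 70, 5)
    np.testing.assert_allclose(T, np.eye(15), atol=1e-12)


def test_transition_rows_sum_to_one():
    T = transition_matrix(3.7, 70, 8)
    np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
    assert (T >= 0).all()


def test_transition_large_distance_stationary():
    """d -> inf: every row is the Hardy-Weinberg diplotype distribution."""
    F = 4
    T = transition_matrix(1e6, 10, F)
    states, het = diplotype_states(F)
    expected = np.array([2.0 / F**2 if h else 1.0 / F**2 for h in het])
    for row in T:
        np.testing.assert_allclose(row, expected, atol=1e-9)


def test_transition_matches_ordered_kernel_product():
    """F=3, d=10 cM, G=10: collapse of the 9x9 ordered-pair kernel."""
    F, d_cM, G = 3, 10.0, 10
    k = _haplotype_kernel(d_cM / 100.0, G, F)
    ordered = np.kron(k, k)  # ordered pairs (a,b) -> (c,d)
    states, _ = diplotype_states(F)
    T_expected = np.zeros((len(states), len(states)))
    for a, (i, j) in enumerate(states):
        for b, (c, d) in enumerate(states):
            # sum ordered targets mapping to unordered state b, from ordered (i,j)
            targets = {(c, d), (d, c)}
            T_expected[a, b] = sum(
                ordered[i * F + j, x * F + y] for (x, y) in targets
            )
    T = transition_matrix(d_cM, G, F)
    np.testing.assert_allclose(T, T_expected, atol=1e-12)


def test_transition_negative_distance_rejected():
    with pytest.raises(ValueError):
        transition_matrix(-1.0, 70, 3)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------


def test_emission_exact_match():
    assert emission_probability(2, (1, 1), 0.0) == 1.0
    assert emission_probability(1, (1, 1), 0.0) == 0.0


def test_emission_het_middle_genotype():
    eps = 0.01
    expected = (1 - eps) ** 2 + eps**2
    assert emission_probability(1, (0, 1), eps) == pytest.approx(expected, abs=1e-15)


def test_emission_missing_is_one():
    for alleles in [(0, 0), (0, 1), (1, 1)]:
        assert emission_probability(MISSING, alleles, 0.3) == 1.0


def test_emission_enumeration_oracle():
    """Brute-force sum over the four flip combinations."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        eps = rng.uniform(0, 0.5)
        a1, a2 = rng.integers(0, 2, 2)
        g = rng.integers(0, 3)
        expected = 0.0
        for f1 in (0, 1):
            for f2 in (0, 1):
                if (a1 ^ f1) + (a2 ^ f2) == g:
                    expected += (eps if f1 else 1 - eps) * (eps if f2 else 1 - eps)
        assert emission_probability(g, (a1, a2), eps) == pytest.approx(expected, abs=1e-14)


def test_emission_distributions_sum_to_one():
    for eps in (0.0, 0.01, 0.37):
        for alleles in [(0, 0), (0, 1), (1, 1)]:
            total = sum(emission_probability(g, alleles, eps) for g in (0, 1, 2))
            assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Forward-backward vs brute-force path enumeration
# ---------------------------------------------------------------------------


def _tiny_panel(F, cMs, alleles):
    M = len(cMs)
    markers = pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(M)],
            "chrom": "1",
            "pos_bp": np.arange(1, M + 1) * 1000,
            "cM": cMs,
        }
    )
    return FounderPanel(founders=[f"F{i}" for i in range(F)], markers=markers,
                        alleles=np.asarray(alleles))


def _brute_force_posteriors(geno_row, panel, G, eps):
    """Sum over all state paths; independent of the forward-backward code."""
    F = panel.n_founders
    states, het = diplotype_states(F)
    S = len(states)
    M = panel.n_markers
    cM = panel.markers["cM"].to_numpy()
    Ts = [transition_matrix(cM[t + 1] - cM[t], G, F) for t in range(M - 1)]
    init = np.where(het, 2.0, 1.0) / F**2
    post = np.zeros((M, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=M):
        p = init[path[0]]
        for t, s in enumerate(path):
            i, j = states[s]
            a = (panel.alleles[i, t], panel.alleles[j, t])
            g = geno_row[t]
            p *= emission_probability(int(g), a, eps)
            if t > 0:
                p *= Ts[t - 1][path[t - 1], s]
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return post / total, np.log(total)


def test_forward_backward_matches_enumeration():
    F = 3
    alleles = np.array([[0, 1, 0], [1, 0, 0], [1, 1, 1]])
    panel = _tiny_panel(F, [0.0, 5.0, 12.0], alleles)
    geno = np.array([[1, 2, MISSING]])
    probs = forward_backward(geno, panel, generations=15, epsilon=0.01)
    expected, ll = _brute_force_posteriors(geno[0], panel, 15, 0.01)
    np.testing.assert_allclose(probs.probs[0], expected, atol=1e-10)
    assert probs.log_likelihood[0] == pytest.approx(ll, abs=1e-10)


@settings(max_examples=20, deadline=None)
@given(
    seed=st.integers(min_value=0, max_value=10_000),
    F=st.integers(min_value=2, max_value=3),
    M=st.integers(min_value=2, max_value=4),
)
def test_forward_backward_enumeration_property(seed, F, M):
    rng = np.random.default_rng(seed)
    eps = rng.uniform(0.0, 0.4)
    G = rng.uniform(1, 50)
    alleles = rng.integers(0, 2, size=(F, M))
    cMs = np.cumsum(rng.uniform(0.5, 8.0, size=M))
    panel = _tiny_panel(F, cMs, alleles)
    geno = rng.choice([0, 1, 2, MISSING], size=(1, M)).astype(np.int8)
    probs = forward_backward(geno, panel, generations=G, epsilon=eps)
    expected, _ll = _brute_force_posteriors(geno[0], panel, G, eps)
    np.testing.assert_allclose(probs.probs[0], expected, atol=1e-10)


def test_forward_backward_identifiable_limit():
    """Unique founder signatures + no error: posterior pins the true state."""
    F = 4
    M = 8
    # give each founder a unique allele column pattern across markers
    alleles = np.array([[int(b) for b in np.binary_repr(f, width=M)] for f in range(F)])
    panel = _tiny_panel(F, np.linspace(0, 0.01, M), alleles)  # tight markers
    true = (1, 3)
    geno = (alleles[true[0]] + alleles[true[1]])[None, :]
    probs = forward_backward(geno.astype(np.int8), panel, generations=5, epsilon=0.0)
    states, _ = diplotype_states(F)
    idx = states.index(true)
    assert (probs.probs[0, :, idx] >= 0.999).all()


def test_forward_backward_label_permutation_symmetry():
    F = 3
    rng = np.random.default_rng(3)
    alleles = rng.integers(0, 2, size=(F, 4))
    panel = _tiny_panel(F, [0, 3, 7, 9], alleles)
    geno = rng.choice([0, 1, 2], size=(2, 4)).astype(np.int8)
    probs = forward_backward(geno, panel, generations=20, epsilon=0.05)

    perm = np.array([2, 0, 1])  # founder relabeling
    panel_p = _tiny_panel(F, [0, 3, 7, 9], alleles[perm])
    probs_p = forward_backward(geno, panel_p, generations=20, epsilon=0.05)

    states, _ = diplotype_states(F)
    # founder f in the permuted panel is founder perm[f] of the original
    for s, (i, j) in enumerate(states):
        mapped = tuple(sorted((perm[i], perm[j])))
        s_orig = states.index(mapped)
        np.testing.assert_allclose(
            probs_p.probs[:, :, s], probs.probs[:, :, s_orig], atol=1e-12
        )


def test_forward_backward_all_missing_warns_uniform():
    panel = _tiny_panel(2, [0.0, 5.0], np.array([[0, 1], [1, 0]]))
    geno = np.full((1, 2), MISSING, dtype=np.int8)
    with pytest.warns(UserWarning, match="all genotypes missing"):
        probs = forward_backward(geno, panel, generations=10, epsilon=0.01)
    # with no data the posterior is the stationary Hardy-Weinberg marginal
    np.testing.assert_allclose(probs.probs[0, :, :], [[0.25, 0.5, 0.25]] * 2, atol=1e-12)


def test_forward_backward_simplex_invariant(small_pop):
    probs = forward_backward(
        small_pop.genotypes[:20], small_pop.panel, generations=25, epsilon=0.002
    )
    np.testing.assert_allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)
    assert (probs.probs >= -1e-12).all()
    assert np.isfinite(probs.log_likelihood).all()


def test_mosaic_recovery_rate():
    """Posterior-mode ancestry matches simulated truth at >= 95% of markers."""
    from hsqtl.simulate import SimConfig, simulate_population
    from hsqtl.hmm import posterior_mode_states

    cfg = SimConfig(
        n_animals=40, chromosomes=[("1", 15.0, 500)], n_founders=8,
        n_generations=70, genotyping_error=0.005, seed=42,
    )
    pop = simulate_population(cfg)
    probs = forward_backward(pop.genotypes, pop.panel, generations=70, epsilon=0.005)
    states, _ = diplotype_states(8)
    lookup = {pair: k for k, pair in enumerate(states)}
    true_state = np.empty((40, 500), dtype=int)
    for a in range(40):
        for m in range(500):
            fs = np.flatnonzero(pop.dose[a, m] > 0)
            pair = (fs[0], fs[0]) if len(fs) == 1 else (fs[0], fs[1])
            true_state[a, m] = lookup[pair]
    match = (posterior_mode_states(probs) == true_state).mean()
    assert match >= 0.95


# ---------------------------------------------------------------------------
# Dosages
# ---------------------------------------------------------------------------


def test_dosage_point_mass_homozygous():
    states, _ = diplotype_states(4)
    probs = np.zeros((1, 1, len(states)))
    probs[0, 0, states.index((2, 2))] = 1.0
    dose = dosages_from_probs(DiplotypeProbs(states=states, probs=probs))
    expected = np.zeros(4)
    expected[2] = 2.0
    np.testing.assert_allclose(dose.dose[0, 0], expected)


def test_dosage_uniform_posterior_is_2_over_F():
    for F in (2, 3, 8):
        states, _ = diplotype_states(F)
        probs = np.full((1, 1, len(states)), 1.0 / len(states))
        dose = dosages_from_probs(DiplotypeProbs(states=states, probs=probs))
        # uniform over unordered states is NOT uniform over founders; the
        # exchangeable-founder uniform corresponds to HW weights
        het = np.array([i != j for i, j in states], dtype=float)
        hw = np.where(het, 2.0 / F**2, 1.0 / F**2)
        probs_hw = np.broadcast_to(hw, (1, 1, len(states))).copy()
        dose_hw = dosages_from_probs(DiplotypeProbs(states=states, probs=probs_hw))
        np.testing.assert_allclose(dose_hw.dose[0, 0], 2.0 / F, atol=1e-12)
        np.testing.assert_allclose(dose.dose.sum(), 2.0, atol=1e-12)


def test_snp_dosage_monomorphic_marker_is_two(small_pop):
    panel = small_pop.panel
    states, _ = diplotype_states(panel.n_founders)
    rng = np.random.default_rng(0)
    p = rng.dirichlet(np.ones(len(states)), size=(3, panel.n_markers))
    probs = DiplotypeProbs(states=states, probs=p)
    dose = dosages_from_probs(probs)
    panel_mono = FounderPanel(
        founders=panel.founders,
        markers=panel.markers,
        alleles=np.ones_like(panel.alleles),
    )
    sd = snp_dosage(dose, panel_mono)
    np.testing.assert_allclose(sd, 2.0, atol=1e-9)


def test_dosage_sum_invariant(small_pop):
    probs = forward_backward(
        small_pop.genotypes[:10], small_pop.panel, generations=25, epsilon=0.002
    )
    dose = dosages_from_probs(probs)
    np.testing.assert_allclose(dose.dose.sum(axis=2), 2.0, atol=1e-9)
    sd = snp_dosage(dose, small_pop.panel)
    assert (sd >= 0).all() and (sd <= 2).all()
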