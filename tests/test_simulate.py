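"""Tests for the synthetic population generator."""

import numpy as np
import pytest
from scipy import stats

from hsqtl.lmm import kinship_from_dosages
from hsqtl.simulate import (
    SimConfig,
    TruthRecord,
    family_kinship,
    simulate_expression,
    simulate_genotypes,
    simulate_mosaics,
    simulate_panel,
    simulate_phenotype,
    simulate_population,
    true_dosage,
)


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------


def test_config_rejects_bad_values():
    with pytest.raises(ValueError):
        SimConfig(n_animals=10, chromosomes=[("1", 50.0, 10)], n_founders=1)
    with pytest.raises(ValueError):
        SimConfig(n_animals=10, chromosomes=[("1", -5.0, 10)])
    with pytest.raises(ValueError):
        SimConfig(n_animals=10, chromosomes=[("1", 50.0, 10)], genotyping_error=1.5)


def test_truth_record_validation():
    with pytest.raises(ValueError):
        TruthRecord(qtl_spec=[(0, np.ones(8), 0.7)], h2_target=0.5)  # sums > 1
    with pytest.raises(ValueError):
        TruthRecord(mediation_scenario="bogus")
    TruthRecord(qtl_spec=[(0, np.ones(8), 0.2)], h2_target=0.45)  # ok


# ---------------------------------------------------------------------------
# Mosaics
# ---------------------------------------------------------------------------


def test_zero_generations_single_segment():
    cfg = SimConfig(n_animals=30, chromosomes=[("1", 80.0, 10)], n_generations=0, seed=1)
    mos = simulate_mosaics(cfg)
    assert (mos.jump_counts() == 0).all()
    for a in range(30):
        for h in range(2):
            assert len(mos.segments(a, 0, h)) == 1


def test_jump_counts_poisson_oracle():
    """G=70 on a 1 Morgan chromosome: mean jumps ~ Poisson(70) over 10,000
    haplotypes, within 3 standard errors."""
    cfg = SimConfig(
        n_animals=5000, chromosomes=[("1", 100.0, 2)], n_generations=70, seed=2
    )
    mos = simulate_mosaics(cfg)
    counts = mos.jump_counts()[:, 0, :].ravel()  # 10,000 haplotypes
    se = np.sqrt(70.0 / counts.size)
    assert abs(counts.mean() - 70.0) < 3 * se
    # variance should also look Poisson (loose sanity band)
    assert 60.0 < counts.var() < 80.0


def test_founder_frequency_uniform():
    """Marginal founder frequency ~ 1/F at an arbitrary position."""
    cfg = SimConfig(n_animals=2000, chromosomes=[("1", 50.0, 2)], seed=3)
    mos = simulate_mosaics(cfg)
    founders = mos.founder_at(0, np.array([17.3]))  # (n, 1, 2)
    counts = np.bincount(founders.ravel(), minlength=8)
    chi2 = stats.chisquare(counts).statistic
    p = stats.chi2.sf(chi2, df=7)
    assert p > 0.001


def test_mosaics_reproducible():
    cfg = SimConfig(n_animals=5, chromosomes=[("1", 50.0, 5)], seed=9)
    a, b = simulate_mosaics(cfg), simulate_mosaics(cfg)
    for i in range(5):
        for h in range(2):
            np.testing.assert_array_equal(a.breaks[i][0][h], b.breaks[i][0][h])
            np.testing.assert_array_equal(a.founders[i][0][h], b.founders[i][0][h])


# ---------------------------------------------------------------------------
# Panel and genotypes
# ---------------------------------------------------------------------------


def test_panel_always_informative():
    cfg = SimConfig(n_animals=2, chromosomes=[("1", 50.0, 300)], seed=4)
    panel = simulate_panel(cfg)
    # no marker monomorphic across founders
    assert (panel.alleles.min(axis=0) != panel.alleles.max(axis=0)).all()
    pos = panel.markers["pos_bp"].to_numpy()
    assert (np.diff(pos) > 0).all()


def test_genotypes_deterministic_without_error():
    cfg = SimConfig(n_animals=20, chromosomes=[("1", 40.0, 30)], seed=6)
    mos = simulate_mosaics(cfg)
    panel = simulate_panel(cfg)
    geno = simulate_genotypes(mos, panel, epsilon=0.0, missing_rate=0.0, rng=0)
    dose = true_dosage(mos, panel)
    expected = np.einsum("imf,fm->im", dose, panel.alleles.astype(float))
    np.testing.assert_array_equal(geno, expected.astype(np.int8))


def test_genotypes_flip_fraction_binomial_oracle():
    """epsilon=0.01 over ~1e5 allele draws: flip fraction within 3 SE."""
    cfg = SimConfig(n_animals=100, chromosomes=[("1", 40.0, 500)], seed=7)
    mos = simulate_mosaics(cfg)
    panel = simulate_panel(cfg)
    clean = simulate_genotypes(mos, panel, epsilon=0.0, rng=0)
    noisy = simulate_genotypes(mos, panel, epsilon=0.01, rng=1)
    # each flipped allele changes the genotype by +-1; compare totals
    n_alleles = 2 * clean.size
    flips = np.abs(noisy.astype(int) - clean.astype(int)).sum()
    p_hat = flips / n_alleles
    se = np.sqrt(0.01 * 0.99 / n_alleles)
    # a small fraction of double flips cancel within a genotype; allow for it
    assert abs(p_hat - 0.01) < 3 * se + 2 * 0.01**2


def test_genotypes_maximal_noise_destroys_signal():
    cfg = SimConfig(n_animals=150, chromosomes=[("1", 40.0, 200)], seed=8)
    mos = simulate_mosaics(cfg)
    panel = simulate_panel(cfg)
    clean = simulate_genotypes(mos, panel, epsilon=0.0, rng=0).astype(float)
    noisy = simulate_genotypes(mos, panel, epsilon=0.5, rng=1).astype(float)
    cors = []
    for m in range(200):
        if clean[:, m].std() > 0 and noisy[:, m].std() > 0:
            cors.append(np.corrcoef(clean[:, m], noisy[:, m])[0, 1])
    assert abs(np.mean(cors)) < 0.05


def test_genotypes_missing_rate():
    cfg = SimConfig(n_animals=100, chromosomes=[("1", 40.0, 200)], seed=8)
    mos = simulate_mosaics(cfg)
    panel = simulate_panel(cfg)
    geno = simulate_genotypes(mos, panel, missing_rate=0.1, rng=2)
    frac = (geno == -1).mean()
    assert abs(frac - 0.1) < 0.01


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def test_phenotype_pure_noise():
    dose = np.zeros((300, 1, 8))
    K = np.eye(300)
    y = simulate_phenotype(dose, K, TruthRecord(h2_target=0.0), rng=0)
    assert y.var() == pytest.approx(1.0, abs=1e-9)
    # no kinship structure: regression of y on any fixed structure ~ 0
    assert abs(y.mean()) < 1e-9


def test_phenotype_qtl_fraction_oracle():
    """Realized QTL variance fraction matches the target (50 reps, n=1000)."""
    cfg = SimConfig(n_animals=1000, chromosomes=[("1", 40.0, 30)], seed=10)
    pop = simulate_population(cfg)
    effects = np.array([1.0, -1.0, 0.5, 0.0, 0.0, 0.2, -0.3, 0.7])
    fracs = []
    for rep in range(50):
        truth = TruthRecord(qtl_spec=[(10, effects, 0.20)], h2_target=0.3)
        rng = np.random.default_rng(rep)
        y = simulate_phenotype(pop.dose, np.eye(1000), truth, rng)
        # independent decomposition: project the QTL component back out
        q = pop.dose[:, 10, :] @ effects
        q = (q - q.mean()) / q.std()
        beta = np.cov(y, q)[0, 1] / q.var()
        fracs.append(beta**2 * q.var() / y.var())
    assert abs(np.mean(fracs) - 0.20) < 0.03


def test_phenotype_equal_effects_contribute_nothing():
    cfg = SimConfig(n_animals=200, chromosomes=[("1", 40.0, 10)], seed=11)
    pop = simulate_population(cfg)
    truth = TruthRecord(qtl_spec=[(3, np.ones(8) * 2.5, 0.5)], h2_target=0.0)
    y1 = simulate_phenotype(pop.dose, np.eye(200), truth, rng=7)
    truth0 = TruthRecord(qtl_spec=[], h2_target=0.0)
    y0 = simulate_phenotype(pop.dose, np.eye(200), truth0, rng=7)
    # founder doses sum to 2, so equal effects are constant: same phenotype
    np.testing.assert_allclose(y1, y0, atol=1e-12)


def test_phenotype_polygenic_fraction():
    K = family_kinship(40, 5, 0.6)
    truth = TruthRecord(h2_target=0.45)
    y = simulate_phenotype(np.zeros((200, 1, 8)), K, truth, rng=3)
    # components are scaled exactly but are not orthogonal in-sample
    assert y.var() == pytest.approx(1.0, abs=0.2)
    # family means carry the polygenic signal: between-family variance is
    # inflated relative to an unstructured trait
    fam_means = y.reshape(40, 5).mean(axis=1)
    assert fam_means.var() > 1.0 / 5.0  # iid would give ~0.2


def test_phenotype_rejects_bad_kinship():
    truth = TruthRecord(h2_target=0.45)
    with pytest.raises(ValueError, match="singular"):
        simulate_phenotype(np.zeros((50, 1, 8)), np.zeros((50, 50)), truth, rng=0)
    with pytest.raises(ValueError):
        simulate_phenotype(np.zeros((50, 1, 8)), np.eye(49), truth, rng=0)


# ---------------------------------------------------------------------------
# Expression scenarios
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def med_pop():
    cfg = SimConfig(
        n_animals=245, chromosomes=[("1", 60.0, 60), ("2", 60.0, 60)],
        n_generations=25, genotyping_error=0.0, seed=12,
    )
    pop = simulate_population(cfg)
    K = kinship_from_dosages(pop.dose).values
    return pop, K


def test_expression_none_scenario_no_cis_signal(med_pop):
    pop, K = med_pop
    esim = simulate_expression(30, pop.dose, pop.panel, K, "none", rng=0, n_decoys=30)
    x = pop.dose[:, 30, :] @ np.r_[1.0, np.zeros(7)]
    max_r = 0.0
    for g in esim.counts.index:
        vals = esim.counts.loc[g].to_numpy(dtype=float)
        if vals.std() > 0:
            max_r = max(max_r, abs(np.corrcoef(x, vals)[0, 1]))
    # Bonferroni-ish null bound for ~34 genes at n=245
    assert max_r < 4.5 / np.sqrt(245)


def test_expression_full_mediation_d_separation(med_pop):
    """Partial correlation of marker and trait given the mediator ~ 0."""
    pop, K = med_pop
    esim = simulate_expression(30, pop.dose, pop.panel, K, "full_mediation", rng=1)
    x = pop.dose[:, 30, :] @ np.r_[1.0, np.zeros(7)]
    g = esim.counts.loc["G_med"].to_numpy(dtype=float)
    y = esim.phenotype
    rxy = np.corrcoef(x, y)[0, 1]
    rxg = np.corrcoef(x, g)[0, 1]
    rgy = np.corrcoef(g, y)[0, 1]
    partial = (rxy - rxg * rgy) / np.sqrt((1 - rxg**2) * (1 - rgy**2))
    assert abs(rxy) > 0.25  # the chain transmits marker -> trait
    assert abs(partial) < abs(rxy) / 2  # conditioning collapses it


def test_expression_zero_inflated_decoy_fails_filter(med_pop):
    from hsqtl.mediation import expression_filter

    pop, K = med_pop
    esim = simulate_expression(30, pop.dose, pop.panel, K, "none", rng=2)
    assert not expression_filter(esim.counts, "G_zero0")
    assert expression_filter(esim.counts, "G_decoy0")


def test_expression_unknown_scenario_rejected(med_pop):
    pop, K = med_pop
    with pytest.raises(ValueError, match="unknown mediation scenario"):
        simulate_expression(30, pop.dose, pop.panel, K, "bogus", rng=0)


# ---------------------------------------------------------------------------
# Determinism and helpers
# ---------------------------------------------------------------------------


def test_population_seed_determinism():
    cfg = SimConfig(n_animals=15, chromosomes=[("1", 40.0, 25)], seed=77,
                    genotyping_error=0.01, missing_rate=0.02)
    a, b = simulate_population(cfg), simulate_population(cfg)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    np.testing.assert_array_equal(a.dose, b.dose)
    np.testing.assert_array_equal(a.panel.alleles, b.panel.alleles)


def test_family_kinship_psd():
    K = family_kinship(10, 4, 0.5)
    w = np.linalg.eigvalsh(K)
    assert w.min() > 0
    np.testing.assert_allclose(np.diag(K), 1.0)
    with pytest.raises(ValueError):
        family_kinship(10, 4, 1.2)
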