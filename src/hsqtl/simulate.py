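"""Synthetic multiparental populations with known ground truth.

Generates HS-like data with the statistical structure the inference modules
assume: founder-ancestry mosaics from a Markov jump process, array genotypes
with per-allele error and missingness, phenotypes with controlled polygenic
and QTL variance fractions, and expression traits with cis-eQTL that do or
do not mediate a QTL.  Every stage records its truth so parameter recovery
can be tested without external data.

All randomness flows from a single master seed; sub-streams are derived
deterministically with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hsqtl.hmm import MISSING, FounderPanel
from hsqtl.prep import rank_inverse_normal

__all__ = [
    "SimConfig",
    "TruthRecord",
    "Mosaics",
    "simulate_mosaics",
    "simulate_panel",
    "simulate_genotypes",
    "true_dosage",
    "simulate_phenotype",
    "simulate_expression",
    "simulate_population",
]

MEDIATION_SCENARIOS = ("full_mediation", "colocal_no_mediation", "partial_mediation", "none")

# default physical scale: 2 cM per Mb, so 1 cM = 500 kb
_BP_PER_CM = 500_000


@dataclass
class SimConfig:
    """Parameters of a synthetic HS-like population.

    ``chromosomes`` is a list of ``(name, length_cM, n_markers)``.  The
    genetic map is uniform within each chromosome unless marker positions are
    supplied explicitly via :func:`simulate_panel`.
    """

    n_animals: int
    chromosomes: list[tuple[str, float, int]]
    n_founders: int = 8
    n_generations: float = 70.0
    genotyping_error: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError(f"n_founders must be >= 2, got {self.n_founders}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        for name, length, n_mark in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r}: length must be > 0")
            if n_mark < 1:
                raise ValueError(f"chromosome {name!r}: needs at least one marker")
        for p, what in ((self.genotyping_error, "genotyping_error"),
                        (self.missing_rate, "missing_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{what} must be in [0, 1], got {p}")


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated phenotype.

    ``qtl_spec`` is a list of ``(marker_index, founder_effects, variance_fraction)``
    where ``founder_effects`` has one additive effect per founder and
    ``variance_fraction`` is the target share of phenotypic variance.
    """

    qtl_spec: list[tuple[int, np.ndarray, float]] = field(default_factory=list)
    h2_target: float = 0.0
    mediation_scenario: str = "none"

    def __post_init__(self) -> None:
        total = self.h2_target
        for _, _, frac in self.qtl_spec:
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"QTL variance fraction {frac} outside [0, 1)")
            total += frac
        if not 0.0 <= self.h2_target < 1.0 + 1e-12:
            raise ValueError(f"h2_target {self.h2_target} outside [0, 1)")
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"variance fractions sum to {total:.3f} > 1 (h2 + QTL shares)"
            )
        if self.mediation_scenario not in MEDIATION_SCENARIOS:
            raise ValueError(
                f"unknown mediation scenario {self.mediation_scenario!r}; "
                f"choose from {MEDIATION_SCENARIOS}"
            )


# ---------------------------------------------------------------------------
# Ancestry mosaics
# ---------------------------------------------------------------------------


@dataclass
class Mosaics:
    """Founder-ancestry mosaics for both haplotypes of every animal.

    For animal ``a``, chromosome ``c``, haplotype ``h`` (0/1):
    ``breaks[a][c][h]`` holds the sorted jump positions in cM (possibly
    including jumps back to the same founder — they are kept, so the break
    count equals the number of jump-process events) and
    ``founders[a][c][h]`` the founder index on each of the
    ``len(breaks)+1`` segments.
    """

    chrom_names: list[str]
    lengths_cM: list[float]
    breaks: list  # [animal][chrom][hap] -> float array
    founders: list  # [animal][chrom][hap] -> int array

    @property
    def n_animals(self) -> int:
        return len(self.breaks)

    def jump_counts(self) -> np.ndarray:
        """Number of jump events per (animal, chromosome, haplotype)."""
        n, C = self.n_animals, len(self.chrom_names)
        out = np.zeros((n, C, 2), dtype=int)
        for a in range(n):
            for c in range(C):
                for h in range(2):
                    out[a, c, h] = len(self.breaks[a][c][h])
        return out

    def founder_at(self, chrom_index: int, positions_cM: np.ndarray) -> np.ndarray:
        """Founder index at each query position: ``(n_animals, n_pos, 2)``."""
        pos = np.asarray(positions_cM, dtype=float)
        out = np.empty((self.n_animals, len(pos), 2), dtype=int)
        for a in range(self.n_animals):
            for h in range(2):
                br = self.breaks[a][chrom_index][h]
                fo = self.founders[a][chrom_index][h]
                out[a, :, h] = fo[np.searchsorted(br, pos, side="right")]
        return out

    def segments(self, animal: int, chrom_index: int, hap: int) -> list[tuple[float, float, int]]:
        """(start_cM, end_cM, founder) triples, unmerged."""
        br = self.breaks[animal][chrom_index][hap]
        fo = self.founders[animal][chrom_index][hap]
        edges = np.concatenate(([0.0], br, [self.lengths_cM[chrom_index]]))
        return [(float(edges[k]), float(edges[k + 1]), int(fo[k])) for k in range(len(fo))]


def simulate_mosaics(config: SimConfig, rng: np.random.Generator | None = None) -> Mosaics:
    """Draw ancestry mosaics from the jump process.

    Each haplotype starts from a uniform founder; jump events arrive as a
    Poisson process with rate ``n_generations`` per Morgan and each event
    redraws the founder uniformly (self-jumps allowed).  The two haplotypes
    of an animal are independent.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    F, G = config.n_founders, config.n_generations
    names = [c[0] for c in config.chromosomes]
    lengths = [float(c[1]) for c in config.chromosomes]
    breaks, founders = [], []
    for _ in range(config.n_animals):
        a_breaks, a_founders = [], []
        for length in lengths:
            c_breaks, c_founders = [], []
            for _h in range(2):
                n_jumps = rng.poisson(G * length / 100.0)
                pos = np.sort(rng.uniform(0.0, length, size=n_jumps))
                fo = rng.integers(0, F, size=n_jumps + 1)
                c_breaks.append(pos)
                c_founders.append(fo)
            a_breaks.append(c_breaks)
            a_founders.append(c_founders)
        breaks.append(a_breaks)
        founders.append(a_founders)
    return Mosaics(chrom_names=names, lengths_cM=lengths, breaks=breaks, founders=founders)


# ---------------------------------------------------------------------------
# Founder panel and genotypes
# ---------------------------------------------------------------------------


def simulate_panel(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    founder_names: list[str] | None = None,
) -> FounderPanel:
    """Random informative founder panel on a uniform genetic map.

    Every marker receives a random biallelic pattern over founders with at
    least one contrast (markers monomorphic across founders are never
    emitted, mirroring informative-marker filtering).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    F = config.n_founders
    if founder_names is None:
        founder_names = [f"F{i}" for i in range(F)]
    rows = []
    allele_cols = []
    for name, length, n_mark in config.chromosomes:
        cM = np.linspace(0.0, length, n_mark) if n_mark > 1 else np.array([length / 2.0])
        bp = np.round(cM * _BP_PER_CM).astype(int) + 1
        bp = np.maximum.accumulate(bp)  # guard against rounding collisions
        bp += np.arange(n_mark)  # strictly increasing even at identical cM
        for k in range(n_mark):
            rows.append((f"{name}_m{k}", name, int(bp[k]), float(cM[k])))
        pat = rng.integers(0, 2, size=(n_mark, F))
        mono = (pat == pat[:, [0]]).all(axis=1)
        while mono.any():
            pat[mono] = rng.integers(0, 2, size=(int(mono.sum()), F))
            mono = (pat == pat[:, [0]]).all(axis=1)
        allele_cols.append(pat.T)
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "cM"])
    alleles = np.concatenate(allele_cols, axis=1)
    return FounderPanel(founders=founder_names, markers=markers, alleles=alleles)


def _mosaic_founder_matrix(mosaics: Mosaics, panel: FounderPanel) -> np.ndarray:
    """True founder index per (animal, marker, haplotype)."""
    n, M = mosaics.n_animals, panel.n_markers
    out = np.empty((n, M, 2), dtype=int)
    for ci, chrom in enumerate(panel.chromosomes()):
        if chrom not in mosaics.chrom_names:
            raise ValueError(f"panel chromosome {chrom!r} absent from mosaics")
        cols = panel.marker_index(chrom)
        cM = panel.markers["cM"].to_numpy()[cols]
        out[:, cols, :] = mosaics.founder_at(mosaics.chrom_names.index(chrom), cM)
    return out


def true_dosage(mosaics: Mosaics, panel: FounderPanel) -> np.ndarray:
    """Ground-truth founder dose matrix ``(n_animals, M, F)`` with 0/1/2 entries."""
    fm = _mosaic_founder_matrix(mosaics, panel)
    n, M, _ = fm.shape
    F = panel.n_founders
    dose = np.zeros((n, M, F))
    for h in range(2):
        idx = fm[:, :, h]
        np.add.at(dose, (np.arange(n)[:, None], np.arange(M)[None, :], idx), 1.0)
    return dose


def simulate_genotypes(
    mosaics: Mosaics,
    panel: FounderPanel,
    epsilon: float = 0.0,
    missing_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Array genotypes from mosaics: allele sums with flip error and missingness.

    Each transmitted allele is flipped independently with probability
    ``epsilon``; calls are then masked missing (-1) with ``missing_rate``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fm = _mosaic_founder_matrix(mosaics, panel)  # (n, M, 2)
    alleles = panel.alleles  # (F, M)
    obs = alleles[fm, np.arange(panel.n_markers)[None, :, None]].astype(np.int8)
    if epsilon > 0:
        flips = rng.random(obs.shape) < epsilon
        obs = np.where(flips, 1 - obs, obs)
    geno = obs.sum(axis=2).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING
    return geno


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _scaled_component(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center ``x`` and scale its sample variance to ``target_var``.

    A constant component contributes zero regardless of the target (no
    allelic contrast means no variance to scale up).
    """
    xc = x - x.mean()
    v = xc.var()
    if v == 0.0 or target_var == 0.0:
        return np.zeros_like(xc)
    return xc * np.sqrt(target_var / v)


def simulate_phenotype(
    dose: np.ndarray,
    kinship: np.ndarray,
    truth: TruthRecord,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Phenotype with exact in-sample variance decomposition.

    ``y`` = sum of QTL additive haplotype effects + a polygenic draw with
    covariance proportional to ``kinship`` + independent noise, each component
    rescaled so the realized (sample) QTL and polygenic variance fractions
    equal their targets and total variance is 1.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = dose.shape[0]
    if kinship.shape != (n, n):
        raise ValueError(f"kinship shape {kinship.shape} does not match {n} animals")
    y = np.zeros(n)
    v_qtl_total = 0.0
    for marker_idx, effects, frac in truth.qtl_spec:
        effects = np.asarray(effects, dtype=float)
        q = dose[:, marker_idx, :] @ effects
        y += _scaled_component(q, frac)
        if np.ptp(q) > 0:
            v_qtl_total += frac
    if truth.h2_target > 0:
        w, U = np.linalg.eigh(kinship)
        if w.min() < -1e-8:
            raise ValueError("kinship matrix is not positive semi-definite")
        g = U @ (np.sqrt(np.clip(w, 0.0, None)) * rng.standard_normal(n))
        if g.var() == 0.0:
            raise ValueError("kinship matrix is singular: polygenic draw is degenerate")
        y += _scaled_component(g, truth.h2_target)
        v_poly = truth.h2_target
    else:
        v_poly = 0.0
    v_noise = max(1.0 - v_poly - v_qtl_total, 0.0)
    e = rng.standard_normal(n)
    if v_noise > 0:
        y += _scaled_component(e, v_noise)
    return y


# ---------------------------------------------------------------------------
# Expression / mediation scenarios
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSim:
    """A simulated expression panel plus the phenotype consistent with it."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    annotations: pd.DataFrame  # gene, chrom, start_bp, end_bp
    phenotype: np.ndarray
    truth: dict


def _poisson_counts(latent: np.ndarray, rng: np.random.Generator,
                    base_mean: float = 100.0, slope: float = 0.6) -> np.ndarray:
    z = (latent - latent.mean()) / (latent.std() or 1.0)
    return rng.poisson(np.exp(np.log(base_mean) + slope * z))


def simulate_expression(
    qtl_marker: int,
    dose: np.ndarray,
    panel: FounderPanel,
    kinship: np.ndarray,
    scenario: str,
    rng: np.random.Generator | int | None = None,
    h2_target: float = 0.3,
    qtl_fraction: float = 0.35,
    eqtl_strength: float = 2.0,
    n_decoys: int = 5,
    n_distal: int = 2,
    founder_contrast: np.ndarray | None = None,
) -> ExpressionSim:
    """Expression counts and a matching phenotype for one mediation scenario.

    Scenarios
    ---------
    ``full_mediation``
        The mediator gene tracks the founder-dosage contrast at the QTL
        marker and the phenotype is generated from the *measured* mediator
        expression, so conditioning on it d-separates marker and trait.
    ``colocal_no_mediation``
        The gene has a cis-eQTL at the marker but the phenotype depends on
        the marker directly (the low-expression/no-path pattern).
    ``partial_mediation``
        The phenotype takes both a direct marker path and a mediator path.
    ``none``
        All genes are decoys; no gene associates with the marker.

    Every scenario also emits local decoy genes (expressed, no cis-eQTL),
    zero-inflated decoys with ~80% zeros (fail the nonzero-expression
    filter), and distal genes on another chromosome.
    """
    if scenario not in MEDIATION_SCENARIOS:
        raise ValueError(
            f"unknown mediation scenario {scenario!r}; choose from {MEDIATION_SCENARIOS}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n, _M, F = dose.shape
    if founder_contrast is None:
        founder_contrast = np.zeros(F)
        founder_contrast[0] = 1.0  # one raised founder at the locus
    x = dose[:, qtl_marker, :] @ founder_contrast
    x_std = (x - x.mean()) / (x.std() or 1.0)

    genes: dict[str, np.ndarray] = {}
    ann_rows = []
    row = panel.markers.iloc[qtl_marker]
    chrom, pos = row["chrom"], int(row["pos_bp"])
    other_chroms = [c for c in panel.chromosomes() if c != chrom]
    distal_chrom = other_chroms[0] if other_chroms else chrom

    def add_gene(name: str, counts: np.ndarray, g_chrom, start: int, end: int) -> None:
        genes[name] = counts
        ann_rows.append((name, g_chrom, start, end))

    mediator = None
    if scenario != "none":
        latent = eqtl_strength * x_std + rng.standard_normal(n)
        med_counts = _poisson_counts(latent, rng)
        mediator = "G_med"
        add_gene(mediator, med_counts, chrom, max(1, pos - 20_000), pos + 20_000)
        # what the analysis will see after CPM+INT: use ranks of the counts
        g_meas = rank_inverse_normal(med_counts.astype(float))

    truth_record = TruthRecord(h2_target=h2_target, mediation_scenario=scenario)
    poly_plus_noise = (
        _scaled_component(_polygenic_draw(kinship, rng), h2_target)
        + _scaled_component(rng.standard_normal(n), 1.0 - h2_target - qtl_fraction)
    )
    if scenario == "full_mediation":
        y = _scaled_component(g_meas, qtl_fraction) + poly_plus_noise
    elif scenario == "colocal_no_mediation":
        y = _scaled_component(x_std, qtl_fraction) + poly_plus_noise
    elif scenario == "partial_mediation":
        half = qtl_fraction / 2.0
        resid = g_meas - np.polyval(np.polyfit(x_std, g_meas, 1), x_std)
        y = (
            _scaled_component(x_std, half)
            + _scaled_component(resid, half)
            + poly_plus_noise
        )
    else:  # none
        y = _scaled_component(x_std, 0.0) + poly_plus_noise + _scaled_component(
            rng.standard_normal(n), qtl_fraction
        )

    for k in range(n_decoys):
        add_gene(
            f"G_decoy{k}",
            _poisson_counts(rng.standard_normal(n), rng),
            chrom,
            max(1, pos - 150_000 + 30_000 * k),
            pos - 120_000 + 30_000 * k,
        )
    for k in range(2):
        zi = rng.poisson(50.0, size=n) * (rng.random(n) < 0.2)
        add_gene(f"G_zero{k}", zi, chrom, pos + 30_000 * (k + 2), pos + 30_000 * (k + 2) + 5_000)
    for k in range(n_distal):
        add_gene(
            f"G_distal{k}",
            _poisson_counts(rng.standard_normal(n), rng),
            distal_chrom,
            10_000 + 50_000 * k,
            40_000 + 50_000 * k,
        )

    sample_ids = [f"A{i}" for i in range(n)]
    counts = pd.DataFrame(
        np.vstack([genes[g] for g in genes]), index=list(genes), columns=sample_ids
    )
    counts.index.name = "gene"
    ann = pd.DataFrame(ann_rows, columns=["gene", "chrom", "start_bp", "end_bp"])
    truth = {
        "scenario": scenario,
        "mediator": mediator,
        "qtl_marker": int(qtl_marker),
        "h2_target": h2_target,
        "qtl_fraction": qtl_fraction,
        "truth_record": truth_record,
    }
    return ExpressionSim(counts=counts, annotations=ann, phenotype=y, truth=truth)


def family_kinship(n_families: int, family_size: int, relatedness: float = 0.5) -> np.ndarray:
    """Block-diagonal family relatedness matrix (unit diagonal).

    A validation aid: unlike the near-exchangeable kinship of a deeply
    outbred population, a family-block structure has wide eigenvalue spread,
    so variance-component recovery tests are well conditioned and the
    realized polygenic variance fraction maps directly onto
    ``tau2/(tau2 + sigma2)``.
    """
    if not 0.0 <= relatedness < 1.0:
        raise ValueError("relatedness must be in [0, 1)")
    block = np.full((family_size, family_size), relatedness)
    np.fill_diagonal(block, 1.0)
    blocks = [block] * n_families
    K = np.zeros((n_families * family_size, n_families * family_size))
    for i in range(n_families):
        sl = slice(i * family_size, (i + 1) * family_size)
        K[sl, sl] = blocks[i]
    return K


def _polygenic_draw(kinship: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w, U = np.linalg.eigh(kinship)
    if w.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semi-definite")
    return U @ (np.sqrt(np.clip(w, 0.0, None)) * rng.standard_normal(len(w)))


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedPopulation:
    config: SimConfig
    panel: FounderPanel
    mosaics: Mosaics
    genotypes: np.ndarray
    dose: np.ndarray  # true founder doses (n, M, F)
    animals: list[str]


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Mosaics, panel, true doses, and noisy genotypes from one master seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_mosaic, rng_panel, rng_geno = (np.random.default_rng(s) for s in ss.spawn(3))
    mosaics = simulate_mosaics(config, rng_mosaic)
    panel = simulate_panel(config, rng_panel)
    geno = simulate_genotypes(
        mosaics, panel, config.genotyping_error, config.missing_rate, rng_geno
    )
    dose = true_dosage(mosaics, panel)
    animals = [f"A{i}" for i in range(config.n_animals)]
    return SimulatedPopulation(
        config=config, panel=panel, mosaics=mosaics, genotypes=geno, dose=dose, animals=animals
    )
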