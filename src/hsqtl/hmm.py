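"""Founder-diplotype inference along the genome.

An HS animal's genome is a mosaic of segments inherited from the founder
strains.  Given array genotypes and the (inbred) founder allele panel, a
hidden Markov model over unordered founder pairs ("diplotypes") recovers the
posterior mosaic at every marker, from which expected founder doses and
imputed SNP doses follow.

The per-haplotype ancestry process is a Markov jump process with rate ``G``
per Morgan (G = number of outbreeding generations) and a uniform jump target
over founders, i.e. a Haldane-type no-interference model with exchangeable
founders.  The two haplotypes of an animal switch independently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # internal genotype code for a missing call

__all__ = [
    "FounderPanel",
    "DiplotypeProbs",
    "FounderDosage",
    "diplotype_states",
    "transition_matrix",
    "emission_probability",
    "forward_backward",
    "dosages_from_probs",
    "snp_dosage",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class FounderPanel:
    """Founder strains, marker map, and inbred founder alleles.

    Parameters
    ----------
    founders
        Ordered founder strain names (length F).
    markers
        One row per marker with columns ``marker``, ``chrom``, ``pos_bp``
        (1-based), ``cM``; sorted by chromosome then position, positions
        strictly increasing within each chromosome.
    alleles
        ``(F, M)`` array in {0, 1}: the single allele each inbred founder
        carries at each marker.
    """

    founders: list[str]
    markers: pd.DataFrame
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        F, M = self.alleles.shape
        if F != len(self.founders):
            raise ValueError(
                f"allele matrix has {F} rows but {len(self.founders)} founders given"
            )
        if M != len(self.markers):
            raise ValueError(
                f"allele matrix has {M} columns but {len(self.markers)} markers given"
            )
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("founder alleles must be 0/1 (founders are inbred)")
        required = {"marker", "chrom", "pos_bp", "cM"}
        missing = required - set(self.markers.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if not (np.diff(pos) > 0).all():
                idx = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 1
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome "
                    f"{chrom!r} at within-chromosome index {idx}"
                )

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosomes(self) -> list:
        """Chromosome names in map order."""
        return list(dict.fromkeys(self.markers["chrom"]))

    def marker_index(self, chrom) -> np.ndarray:
        """Column indices of the markers on one chromosome."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())


@dataclass
class DiplotypeProbs:
    """Posterior over the F(F+1)/2 unordered founder-pair states.

    ``probs`` has shape ``(n_animals, n_markers, n_states)``; each
    ``probs[i, m]`` is a probability simplex.
    """

    states: list[tuple[int, int]]
    probs: np.ndarray
    animals: list[str] | None = None
    log_likelihood: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != len(self.states):
            raise ValueError("probs must be (animals, markers, states)")
        if (self.probs < -1e-12).any():
            raise ValueError("negative diplotype probabilities")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("diplotype probabilities must sum to 1 per animal/marker")


@dataclass
class FounderDosage:
    """Expected copies of each founder haplotype: ``(n_animals, n_markers, F)``."""

    dose: np.ndarray
    founders: list[str] = field(default_factory=list)
    animals: list[str] | None = None

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if (self.dose < -1e-9).any() or (self.dose > 2 + 1e-9).any():
            raise ValueError("founder doses must lie in [0, 2]")
        if not np.allclose(self.dose.sum(axis=2), 2.0, atol=1e-9):
            raise ValueError("founder doses must sum to 2 per animal/marker")


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------


def diplotype_states(n_founders: int) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Enumerate unordered founder-pair states in canonical order.

    Order: all pairs ``(i, j)`` with ``i <= j``, lexicographic — so for F=3:
    (0,0), (0,1), (0,2), (1,1), (1,2), (2,2).  Returns the state list and a
    boolean heterozygosity flag per state (``i != j``).  There are
    F(F+1)/2 states, of which F(F-1)/2 are heterozygous (28 for F=8).
    """
    if n_founders < 2:
        raise ValueError(f"need at least 2 founders, got {n_founders}")
    states = [
        (i, j) for i in range(n_founders) for j in range(i, n_founders)
    ]
    het = np.array([i != j for i, j in states])
    return states, het


def _haplotype_kernel(d_morgan: float, generations: float, n_founders: int) -> np.ndarray:
    """Single-haplotype founder switch kernel over distance ``d_morgan``.

    P(same) = e^{-G d} + (1 - e^{-G d})/F; P(specific other) = (1 - e^{-G d})/F.
    """
    stay = np.exp(-generations * d_morgan)
    p_other = (1.0 - stay) / n_founders
    k = np.full((n_founders, n_founders), p_other)
    np.fill_diagonal(k, stay + p_other)
    return k


def transition_matrix(d_cM: float, generations: float, n_founders: int) -> np.ndarray:
    """Diplotype transition matrix over a marker interval of ``d_cM``.

    Product of two independent per-haplotype jump kernels, collapsed onto
    unordered states.  Rows sum to 1; ``d_cM = 0`` gives the identity.
    """
    if d_cM < 0:
        raise ValueError(f"negative marker distance: {d_cM}")
    states, _ = diplotype_states(n_founders)
    k = _haplotype_kernel(d_cM / 100.0, generations, n_founders)
    S = len(states)
    T = np.empty((S, S))
    for a, (i, j) in enumerate(states):
        for b, (c, d) in enumerate(states):
            p = k[i, c] * k[j, d]
            if c != d:
                p += k[i, d] * k[j, c]
            T[a, b] = p
    return T


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------


def emission_probability(
    genotype: int, state_alleles: tuple[int, int], epsilon: float
) -> float:
    """P(observed genotype | the two founder alleles), per-allele flip error.

    Each of the two transmitted alleles is observed flipped independently with
    probability ``epsilon``; the genotype is the sum of the observed alleles.
    Missing genotypes contribute likelihood 1.
    """
    if not 0.0 <= epsilon <= 0.5:
        raise ValueError(f"epsilon must be in [0, 0.5], got {epsilon}")
    if genotype == MISSING or genotype is None:
        return 1.0
    if genotype not in (0, 1, 2):
        raise ValueError(f"genotype must be 0/1/2/missing, got {genotype}")
    p = 0.0
    a1, a2 = state_alleles
    for f1 in (0, 1):
        for f2 in (0, 1):
            obs = (a1 ^ f1) + (a2 ^ f2)
            if obs == genotype:
                w1 = epsilon if f1 else 1.0 - epsilon
                w2 = epsilon if f2 else 1.0 - epsilon
                p += w1 * w2
    return p


def _emission_table(alleles_chrom: np.ndarray, epsilon: float) -> np.ndarray:
    """Emission likelihoods for every (marker, state, genotype).

    Returns ``(M, S, 4)``: last axis indexes genotype 0, 1, 2, missing.
    Vectorized counterpart of :func:`emission_probability`.
    """
    F, M = alleles_chrom.shape
    states, _ = diplotype_states(F)
    a1 = alleles_chrom[[i for i, _ in states], :]  # (S, M)
    a2 = alleles_chrom[[j for _, j in states], :]
    e = epsilon
    # per-allele observation distributions: P(obs=1 | true a) = a(1-e) + (1-a)e
    p1_1 = a1 * (1 - e) + (1 - a1) * e
    p2_1 = a2 * (1 - e) + (1 - a2) * e
    tab = np.empty((M, len(states), 4))
    tab[:, :, 0] = ((1 - p1_1) * (1 - p2_1)).T
    tab[:, :, 1] = (p1_1 * (1 - p2_1) + (1 - p1_1) * p2_1).T
    tab[:, :, 2] = (p1_1 * p2_1).T
    tab[:, :, 3] = 1.0
    return tab


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------


def forward_backward(
    genotypes: np.ndarray,
    panel: FounderPanel,
    generations: float = 70.0,
    epsilon: float = 0.01,
    animals: list[str] | None = None,
) -> DiplotypeProbs:
    """Exact marginal diplotype posteriors under the mosaic HMM.

    Parameters
    ----------
    genotypes
        ``(n_animals, M)`` integer matrix in {0, 1, 2, -1(missing)}, marker
        columns aligned with ``panel.markers``.
    panel
        Founder panel; chromosomes are processed independently.  The initial
        state distribution is the jump process's stationary law — the
        Hardy-Weinberg weights over unordered founder pairs (2/F^2 for
        heterozygous states, 1/F^2 for homozygous) — so an uninformative
        chromosome returns the population marginal.
    generations, epsilon
        Jump-process rate per Morgan and per-allele genotyping error rate.

    Returns
    -------
    DiplotypeProbs with per-animal total log-likelihood attached.  Scaled
    forward-backward recursions are used, so chromosomes with tens of
    thousands of markers do not underflow.
    """
    genotypes = np.asarray(genotypes)
    n, M = genotypes.shape
    if M != panel.n_markers:
        raise ValueError(
            f"genotype matrix has {M} markers but panel has {panel.n_markers}"
        )
    F = panel.n_founders
    states, het = diplotype_states(F)
    S = len(states)
    init = np.where(het, 2.0, 1.0) / F**2  # stationary (Hardy-Weinberg) law
    post = np.empty((n, M, S))
    loglik = np.zeros(n)

    geno_idx = genotypes.copy()
    geno_idx[geno_idx == MISSING] = 3  # index into emission table's last axis

    for chrom in panel.chromosomes():
        cols = panel.marker_index(chrom)
        if (genotypes[:, cols] == MISSING).all():
            warnings.warn(
                f"chromosome {chrom!r}: all genotypes missing; posteriors are uniform",
                stacklevel=2,
            )
        emit = _emission_table(panel.alleles[:, cols], epsilon)  # (Mc, S, 4)
        cM = panel.markers["cM"].to_numpy()[cols]
        Ts = [
            transition_matrix(float(d), generations, F) for d in np.diff(cM)
        ]
        Mc = len(cols)
        # observation likelihoods per animal/marker/state
        obs = emit[np.arange(Mc)[None, :], :, geno_idx[:, cols]]  # (n, Mc, S)

        alpha = np.empty((n, Mc, S))
        scale = np.empty((n, Mc))
        a = obs[:, 0, :] * init[None, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0, None]
        for t in range(1, Mc):
            a = (alpha[:, t - 1, :] @ Ts[t - 1]) * obs[:, t, :]
            scale[:, t] = a.sum(axis=1)
            alpha[:, t, :] = a / scale[:, t, None]

        beta = np.empty((n, Mc, S))
        beta[:, -1, :] = 1.0
        for t in range(Mc - 2, -1, -1):
            b = (beta[:, t + 1, :] * obs[:, t + 1, :]) @ Ts[t].T
            beta[:, t, :] = b / scale[:, t + 1, None]

        p = alpha * beta
        p /= p.sum(axis=2, keepdims=True)
        post[:, cols, :] = p
        loglik += np.log(scale).sum(axis=1)

    return DiplotypeProbs(states=states, probs=post, animals=animals, log_likelihood=loglik)


# ---------------------------------------------------------------------------
# Dosages
# ---------------------------------------------------------------------------


def _state_dose_matrix(states: list[tuple[int, int]], n_founders: int) -> np.ndarray:
    """(S, F) matrix: copies of each founder haplotype carried in each state."""
    C = np.zeros((len(states), n_founders))
    for s, (i, j) in enumerate(states):
        C[s, i] += 1
        C[s, j] += 1
    return C


def dosages_from_probs(probs: DiplotypeProbs, founders: list[str] | None = None) -> FounderDosage:
    """Expected founder haplotype doses from diplotype posteriors."""
    F = max(max(s) for s in probs.states) + 1
    C = _state_dose_matrix(probs.states, F)
    dose = probs.probs @ C
    names = founders if founders is not None else [f"F{i}" for i in range(F)]
    return FounderDosage(dose=dose, founders=names, animals=probs.animals)


def snp_dosage(dosage: FounderDosage, panel: FounderPanel) -> np.ndarray:
    """Imputed expected allele-1 dose per animal/marker, in [0, 2].

    The founder doses at each marker are contracted with the founder alleles:
    ``d_snp[i, m] = sum_f dose[i, m, f] * allele[f, m]``.
    """
    if dosage.dose.shape[2] != panel.n_founders:
        raise ValueError("founder count mismatch between dosage and panel")
    if dosage.dose.shape[1] != panel.n_markers:
        raise ValueError("marker count mismatch between dosage and panel")
    d = np.einsum("imf,fm->im", dosage.dose, panel.alleles.astype(float))
    return np.clip(d, 0.0, 2.0)


def posterior_mode_states(probs: DiplotypeProbs) -> np.ndarray:
    """Marginal posterior-mode state index per animal/marker."""
    return probs.probs.argmax(axis=2)
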