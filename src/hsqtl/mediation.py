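"""Four-criterion expression mediation analysis at a detected QTL.

Given a QTL (criterion 1, established upstream by the scan), each gene local
to the LD support interval is evaluated sequentially:

  2. cis-eQTL at the peak — LRT of the peak dose on the gene's (CPM + INT)
     expression, Benjamini-Hochberg FDR 0.1 within the local gene set, after
     a >25% nonzero-expression filter;
  3. full mediation — the peak-dose LRT on the trait with the mediator as a
     covariate in both null and alternative models; conditioned p > 0.05
     makes full mediation plausible;
  4. partial mediation — 1-df LRT for the mediator coefficient in the model
     already containing the peak dose, BH q <= 0.1.

A gene passing criterion 2 and criterion 3 and/or 4 is declared a candidate
mediator.  All computed values are retained for audit even when a gene fails
an earlier gate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hsqtl.lmm import EigenK, KinshipMatrix, fit_lmm
from hsqtl.prep import cpm_normalize, rank_inverse_normal
from hsqtl.scan import QTLInterval

__all__ = [
    "bh_adjust",
    "select_local_genes",
    "expression_filter",
    "cis_eqtl_test",
    "full_mediation_test",
    "partial_mediation_test",
    "mediation_verdict",
    "mediate",
]

VERDICTS = ("not_local", "filtered", "no_cis_eqtl", "candidate_mediator", "not_mediator")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} ( p_(j) * m / j )`` over the sorted p-values,
    capped at 1.  Rejecting ``q <= alpha`` reproduces the BH procedure at
    level ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_local_genes(annotations: pd.DataFrame, interval: QTLInterval) -> pd.Series:
    """Boolean mask: genes overlapping the interval on its chromosome.

    A gene is local if its span ``[start_bp, end_bp]`` overlaps the closed
    interval at all — genes straddling a boundary count as local.
    """
    required = {"gene", "chrom", "start_bp", "end_bp"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"gene annotation table missing columns: {sorted(missing)}")
    same_chrom = annotations["chrom"] == interval.chrom
    overlap = (annotations["start_bp"] <= interval.end_bp) & (
        annotations["end_bp"] >= interval.start_bp
    )
    mask = same_chrom & overlap
    mask.index = annotations["gene"]
    return mask


def expression_filter(expression: pd.DataFrame, gene: str, min_fraction: float = 0.25) -> bool:
    """Pass iff the fraction of samples with value > 0 strictly exceeds 25%."""
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} not found in expression matrix")
    vals = expression.loc[gene].to_numpy(dtype=float)
    return float((vals > 0).mean()) > min_fraction


def _lrt_pvalue(ll_alt: float, ll_null: float) -> float:
    lrt = max(2.0 * (ll_alt - ll_null), 0.0)
    return float(stats.chi2.sf(lrt, df=1))


def cis_eqtl_test(
    expr: np.ndarray, peak_dose: np.ndarray, K: KinshipMatrix | np.ndarray | EigenK
) -> float:
    """LRT p-value for the peak-marker dose effect on one gene's expression.

    ``expr`` must already be INT-transformed; constant expression is an error.
    """
    expr = np.asarray(expr, dtype=float).ravel()
    if np.ptp(expr[~np.isnan(expr)]) == 0:
        raise ValueError("constant expression vector; cis-eQTL test undefined")
    n = expr.size
    eig = K if isinstance(K, EigenK) else EigenK.from_kinship(K)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([X0, peak_dose])
    null = fit_lmm(expr, eig, X=X0)
    alt = fit_lmm(expr, eig, X=X1)
    return _lrt_pvalue(alt.loglik, null.loglik)


def full_mediation_test(
    y: np.ndarray,
    peak_dose: np.ndarray,
    mediator: np.ndarray,
    K: KinshipMatrix | np.ndarray | EigenK,
) -> float:
    """Conditioned QTL p: peak-dose LRT with the mediator in both models."""
    y = np.asarray(y, dtype=float).ravel()
    mediator = np.asarray(mediator, dtype=float).ravel()
    if np.ptp(mediator) == 0:
        raise ValueError("mediator is constant (collinear with the intercept)")
    n = y.size
    eig = K if isinstance(K, EigenK) else EigenK.from_kinship(K)
    X0 = np.column_stack([np.ones(n), mediator])
    X1 = np.column_stack([X0, peak_dose])
    null = fit_lmm(y, eig, X=X0)
    alt = fit_lmm(y, eig, X=X1)
    return _lrt_pvalue(alt.loglik, null.loglik)


def partial_mediation_test(
    y: np.ndarray,
    peak_dose: np.ndarray,
    mediator: np.ndarray,
    K: KinshipMatrix | np.ndarray | EigenK,
) -> float:
    """1-df LRT for the mediator coefficient given the peak-dose effect."""
    y = np.asarray(y, dtype=float).ravel()
    mediator = np.asarray(mediator, dtype=float).ravel()
    if np.ptp(mediator) == 0:
        raise ValueError("mediator is constant (collinear with the intercept)")
    n = y.size
    eig = K if isinstance(K, EigenK) else EigenK.from_kinship(K)
    X0 = np.column_stack([np.ones(n), peak_dose])
    X1 = np.column_stack([X0, mediator])
    null = fit_lmm(y, eig, X=X0)
    alt = fit_lmm(y, eig, X=X1)
    return _lrt_pvalue(alt.loglik, null.loglik)


def mediation_verdict(row: pd.Series) -> str:
    """Map one gene's computed criteria onto its verdict label."""
    if not row["local"]:
        return "not_local"
    if not row["filter_pass"]:
        return "filtered"
    if not (row["cis_q"] <= 0.1):
        return "no_cis_eqtl"
    if bool(row["full_mediation_plausible"]) or (
        np.isfinite(row["partial_q"]) and row["partial_q"] <= 0.1
    ):
        return "candidate_mediator"
    return "not_mediator"


def mediate(
    y: np.ndarray,
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    interval: QTLInterval,
    peak_dose: np.ndarray,
    K: KinshipMatrix | np.ndarray | EigenK,
    fdr: float = 0.1,
    full_mediation_alpha: float = 0.05,
    min_expressed_fraction: float = 0.25,
) -> pd.DataFrame:
    """Run the sequential four-criterion procedure for every gene.

    ``counts`` is a genes x samples matrix aligned with ``y``; expression is
    CPM-normalized and INT-transformed before testing.  Returns one row per
    gene with all computed criteria and the final verdict.  Criteria after a
    failed gate are left NaN (short-circuiting), except that all genes keep
    their locality and filter status for audit.
    """
    eig = K if isinstance(K, EigenK) else EigenK.from_kinship(K)
    local_mask = select_local_genes(annotations, interval)
    cpm = cpm_normalize(counts)

    genes = list(counts.index)
    tbl = pd.DataFrame(
        {
            "gene": genes,
            "local": [bool(local_mask.get(g, False)) for g in genes],
            "filter_pass": False,
            "cis_p": np.nan,
            "cis_q": np.nan,
            "full_p": np.nan,
            "full_mediation_plausible": False,
            "partial_p": np.nan,
            "partial_q": np.nan,
            "degenerate": False,
        }
    ).set_index("gene", drop=False)

    testable = []
    for g in genes:
        if not tbl.loc[g, "local"]:
            continue
        ok = expression_filter(counts, g, min_expressed_fraction)
        tbl.loc[g, "filter_pass"] = ok
        if ok:
            testable.append(g)

    expr_int: dict[str, np.ndarray] = {}
    for g in testable:
        expr_int[g] = rank_inverse_normal(cpm.loc[g].to_numpy(dtype=float))
        tbl.loc[g, "cis_p"] = cis_eqtl_test(expr_int[g], peak_dose, eig)
    if testable:
        qs = bh_adjust(tbl.loc[testable, "cis_p"].to_numpy())
        tbl.loc[testable, "cis_q"] = qs

    mediators = [g for g in testable if tbl.loc[g, "cis_q"] <= fdr]
    for g in mediators:
        med = expr_int[g]
        if abs(np.corrcoef(med, y)[0, 1]) > 0.999:
            tbl.loc[g, "degenerate"] = True
        fp = full_mediation_test(y, peak_dose, med, eig)
        tbl.loc[g, "full_p"] = fp
        tbl.loc[g, "full_mediation_plausible"] = fp > full_mediation_alpha
        tbl.loc[g, "partial_p"] = partial_mediation_test(y, peak_dose, med, eig)
    if mediators:
        tbl.loc[mediators, "partial_q"] = bh_adjust(
            tbl.loc[mediators, "partial_p"].to_numpy()
        )

    tbl["verdict"] = [mediation_verdict(tbl.loc[g]) for g in genes]
    return tbl.reset_index(drop=True)
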