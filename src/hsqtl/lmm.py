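"""Linear mixed model machinery shared by the scan, heritability, founder
effect, and mediation modules.

The model is ``y = X b + u + e`` with ``u ~ N(0, tau2 * K)`` and
``e ~ N(0, sigma2 * I)``.  A single eigendecomposition of the kinship matrix
reduces every likelihood evaluation to diagonal weighted least squares, and
the variance ratio ``lambda = tau2 / sigma2`` is profiled out by 1-D
optimization.  Maximum likelihood is the default so likelihood-ratio tests
of fixed effects are valid; REML is available for variance reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["KinshipMatrix", "LMMFit", "kinship_from_dosages", "fit_lmm", "EigenK"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix with animal ids."""

    values: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError(f"kinship must be square, got shape {K.shape}")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8:
            raise ValueError(f"kinship matrix not PSD: min eigenvalue {w.min():.3g}")
        if (np.diag(K) <= 0).any():
            raise ValueError("kinship diagonal entries must be positive")
        self.values = K
        if self.ids is not None and len(self.ids) != K.shape[0]:
            raise ValueError("id list length does not match kinship dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def kinship_from_dosages(dose: np.ndarray, ids: list[str] | None = None) -> KinshipMatrix:
    """Genomic relatedness from founder haplotype doses.

    ``K = (1 / 2L) * sum_m D_m D_m^T`` over the L markers, where ``D_m`` is
    the centered-free ``n x F`` founder-dose matrix at marker ``m``, then
    rescaled so the mean diagonal is 1.  PSD by construction and invariant
    to founder relabeling.
    """
    if hasattr(dose, "dose"):  # accept a FounderDosage
        ids = ids if ids is not None else getattr(dose, "animals", None)
        dose = dose.dose
    dose = np.asarray(dose, dtype=float)
    n, L, F = dose.shape
    if L == 0:
        raise ValueError("cannot build kinship from zero markers")
    flat = dose.reshape(n, L * F)
    K = flat @ flat.T / (2.0 * L)
    K *= n / np.trace(K)
    return KinshipMatrix(values=K, ids=ids)


@dataclass
class EigenK:
    """Cached eigendecomposition of a kinship matrix (``K = U diag(s) U^T``)."""

    s: np.ndarray
    U: np.ndarray

    @classmethod
    def from_kinship(cls, K: KinshipMatrix | np.ndarray) -> "EigenK":
        mat = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
        s, U = np.linalg.eigh(mat)
        return cls(s=np.clip(s, 0.0, None), U=U)


@dataclass
class LMMFit:
    """Fitted LMM: fixed effects, variance components, likelihood, caches."""

    beta: np.ndarray
    tau2: float
    sigma2: float
    loglik: float
    lam: float  # tau2 / sigma2
    method: str
    eigen: EigenK = field(repr=False)
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.sigma2 < 0:
            raise ValueError("variance components must be nonnegative")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood is not finite")

    @property
    def h2(self) -> float:
        """Point estimate tau2 / (tau2 + sigma2)."""
        tot = self.tau2 + self.sigma2
        return self.tau2 / tot if tot > 0 else 0.0


def _check_design(X: np.ndarray, n: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        raise ValueError(f"design matrix has {X.shape[0]} rows for {n} observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear or zero column)")
    return X


def _profile_loglik(
    log10_lam: float, yr: np.ndarray, Xr: np.ndarray, s: np.ndarray, reml: bool
) -> tuple[float, np.ndarray, float, float]:
    """Profile log-likelihood at a variance ratio, in the rotated basis.

    Returns (loglik, beta_hat, tau2_hat, sigma2_hat).
    """
    lam = 10.0 ** log10_lam
    n, p = Xr.shape
    w = lam * s + 1.0
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(r @ (r / w))
    logdet = float(np.log(w).sum())
    if reml:
        dof = n - p
        sigma2 = rss / dof
        _, ld_xx = np.linalg.slogdet(XtWX)
        ll = -0.5 * (dof * (_LOG_2PI + np.log(sigma2)) + logdet + ld_xx + dof)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (_LOG_2PI + np.log(sigma2)) + logdet + n)
    return ll, beta, lam * sigma2, sigma2


def fit_lmm(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray | EigenK,
    X: np.ndarray | None = None,
    method: str = "ML",
    log10_lam_bounds: tuple[float, float] = (-6.0, 6.0),
    xatol: float = 1e-10,
) -> LMMFit:
    """Fit the LMM by 1-D optimization of the profiled variance ratio.

    Parameters
    ----------
    y
        Response vector (finite, typically INT-transformed).
    K
        Kinship matrix or a precomputed :class:`EigenK`.
    X
        Fixed-effect design including the intercept; defaults to an
        intercept-only design.  Rank-deficient designs are rejected.
    method
        ``"ML"`` (default, valid for likelihood-ratio testing) or ``"REML"``.

    The optimum of the profiled likelihood over ``log10(lambda)`` is located
    with bounded Brent search plus an explicit check of the ``lambda -> 0``
    boundary; the log-likelihood is maximized to ~1e-8 relative tolerance.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if X is None:
        X = np.ones((n, 1))
    X = _check_design(X, n)
    reml = method.upper() == "REML"
    if method.upper() not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")

    eig = K if isinstance(K, EigenK) else EigenK.from_kinship(K)
    if eig.U.shape[0] != n:
        raise ValueError(f"kinship dimension {eig.U.shape[0]} != {n} observations")
    yr = eig.U.T @ y
    Xr = eig.U.T @ X

    def neg(llog: float) -> float:
        return -_profile_loglik(llog, yr, Xr, eig.s, reml)[0]

    res = optimize.minimize_scalar(
        neg, bounds=log10_lam_bounds, method="bounded", options={"xatol": xatol}
    )
    candidates = [res.x, log10_lam_bounds[0], log10_lam_bounds[1]]
    best = min(candidates, key=neg)
    ll, beta, tau2, sigma2 = _profile_loglik(best, yr, Xr, eig.s, reml)
    lam = 10.0 ** best
    if best <= log10_lam_bounds[0] + 1e-9:
        # effectively no polygenic component
        ll0, beta, _t, sigma2 = _profile_loglik(log10_lam_bounds[0], yr, Xr, eig.s, reml)
        tau2, lam, ll = 0.0, 0.0, ll0
    return LMMFit(
        beta=beta, tau2=tau2, sigma2=sigma2, loglik=ll, lam=lam,
        method="REML" if reml else "ML", eigen=eig, X=X, y=y,
    )
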