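"""Reliability and exploratory-factor-analysis layer.

Implements the classical battery-validation toolchain: Cronbach's α,
Kaiser-Meyer-Olkin sampling adequacy, Bartlett's test of sphericity, iterated
principal-axis factoring (PAF), promax rotation after a varimax start, and
the weighted-sum factor scores used in screening-instrument reports.

PAF and the promax pattern/factor-correlation computation are authored here
(the rotation's orthogonal start is statsmodels' varimax); statsmodels'
``Factor``/``promax`` serve as cross-checks in the test suite, not as the
implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "ReliabilityResult",
    "EfaResult",
    "cronbach_alpha",
    "kmo",
    "bartlett_sphericity",
    "principal_axis_factoring",
    "promax_rotation",
    "efa",
    "factor_scores",
    "reliability",
]


@dataclass(frozen=True)
class ReliabilityResult:
    """Internal-consistency and sampling-adequacy summary for an item battery."""

    alpha: float
    kmo_overall: float
    kmo_per_item: np.ndarray
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n_subjects: int
    items: tuple[str, ...] = ()


@dataclass(frozen=True)
class EfaResult:
    """Converged exploratory-factor-analysis solution.

    ``pattern_loadings`` are the oblique pattern coefficients (items ×
    factors, ordered by variance explained, each column signed so its
    largest-|loading| item is positive); ``variance_explained`` holds the
    per-factor percentage of total item variance carried by the squared
    structure loadings.  ``heywood`` flags communalities above 1, which are
    reported, never clipped.
    """

    eigenvalues: np.ndarray
    pattern_loadings: np.ndarray
    factor_correlation: np.ndarray
    variance_explained: np.ndarray
    communalities: np.ndarray
    n_factors: int
    heywood: bool = False
    items: tuple[str, ...] = ()
    factor_names: tuple[str, ...] = ()

    def interpretable(self, threshold: float = 0.30) -> np.ndarray:
        """Boolean mask of loadings large enough to interpret (|λ| > threshold)."""
        return np.abs(self.pattern_loadings) > threshold


def _as_matrix(item_matrix) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(item_matrix, pd.DataFrame):
        return item_matrix.to_numpy(dtype=float), tuple(map(str, item_matrix.columns))
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("item matrix must be 2-dimensional (subjects × items)")
    return X, tuple(f"item_{i + 1}" for i in range(X.shape[1]))


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's α: ``k/(k−1) · (1 − Σ σᵢ² / σ_total²)``.

    Sample variances (``ddof=1``) are used throughout, the convention of
    reliability reporting.  Raises if the total score has no variance, where
    α is undefined.
    """
    X, _ = _as_matrix(item_matrix)
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items and 2 subjects")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score variance is zero; alpha is undefined")
    item_vars = X.var(axis=0, ddof=1)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def _correlation(X: np.ndarray, items: tuple[str, ...]) -> np.ndarray:
    sds = X.std(axis=0, ddof=1)
    dead = [items[i] for i in np.flatnonzero(sds == 0)]
    if dead:
        raise ValueError(f"items with zero variance: {dead}")
    return np.corrcoef(X, rowvar=False)


def kmo(item_matrix) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy, overall and per item.

    Contrasts the off-diagonal raw correlations with the anti-image partial
    correlations: ``KMO = Σ r² / (Σ r² + Σ q²)`` where ``q`` are the partial
    correlations obtained from the inverse correlation matrix.  Values below
    0.6 are conventionally taken to indicate inadequacy for factoring.
    """
    X, items = _as_matrix(item_matrix)
    R = _correlation(X, items)
    if np.linalg.cond(R) > 1e12:
        r_off = np.abs(R - np.eye(len(R)))
        i, j = np.unravel_index(np.argmax(r_off), R.shape)
        raise ValueError(
            "correlation matrix is singular or nearly so; most collinear pair: "
            f"{items[i]!r} and {items[j]!r} (r = {R[i, j]:.6f})"
        )
    S = np.linalg.inv(R)
    d = 1.0 / np.sqrt(np.diag(S))
    partial = -S * np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    r2 = R**2
    np.fill_diagonal(r2, 0.0)
    q2 = partial**2
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    per_item = r2.sum(axis=0) / (r2.sum(axis=0) + q2.sum(axis=0))
    return overall, per_item


def bartlett_sphericity(item_matrix) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    ``χ² = −(n − 1 − (2p + 5)/6) · ln det(R)`` on ``p(p−1)/2`` degrees of
    freedom.  A retained null means the battery is unsuitable for factoring.
    """
    X, items = _as_matrix(item_matrix)
    n, p = X.shape
    if n <= p:
        raise ValueError("Bartlett's test needs more subjects than items")
    R = _correlation(X, items)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Factor extraction and rotation

def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations: 1 − 1/diag(R⁻¹)."""
    return 1.0 - 1.0 / np.diag(np.linalg.inv(R))


def _column_signs(L: np.ndarray) -> np.ndarray:
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def _sign_columns(L: np.ndarray) -> np.ndarray:
    return L * _column_signs(L)


def principal_axis_factoring(
    correlation_matrix: np.ndarray,
    n_factors: int,
    tol: float = 1e-3,
    max_iter: int = 1_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated principal-axis factoring on a correlation matrix.

    Communalities start at the squared multiple correlations, replace the
    diagonal, and are rebuilt from the leading ``n_factors`` eigenpairs until
    the largest absolute change drops below ``tol``.  Returns ``(loadings,
    communalities)``; loadings are eigenvector·√eigenvalue, columns signed so
    the largest-|loading| item is positive.  A Heywood case (communality
    above 1) is reported as a warning, not clipped.

    The default tolerance follows the loose convention of the standard
    factor-analysis packages: batteries with a weakly determined factor
    (e.g. a two-item factor) exhibit an unbounded slow Heywood drift under
    exact iteration, so demanding much tighter convergence on sampled
    correlation matrices is not generally achievable.  Exact low-rank
    constructions do converge tightly when a smaller ``tol`` is passed.
    """
    R = np.asarray(correlation_matrix, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p):
        raise ValueError("correlation matrix must be square")
    if not 1 <= n_factors < p:
        raise ValueError(f"n_factors must be in [1, {p - 1}], got {n_factors}")
    h = _smc(R)
    delta = np.inf
    for _ in range(max_iter):
        R_red = R.copy()
        np.fill_diagonal(R_red, h)
        eigvals, eigvecs = np.linalg.eigh(R_red)
        order = np.argsort(eigvals)[::-1][:n_factors]
        lam = np.clip(eigvals[order], 0.0, None)
        L = eigvecs[:, order] * np.sqrt(lam)
        h_new = (L**2).sum(axis=1)
        delta = np.max(np.abs(h_new - h))
        h = h_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"principal-axis factoring did not converge in {max_iter} iterations "
            f"(last communality change {delta:.3e})"
        )
    if np.any(h > 1.0 + 1e-10):
        warnings.warn("Heywood case: communality above 1", RuntimeWarning, stacklevel=2)
    return _sign_columns(L), h


def promax_rotation(
    unrotated_loadings: np.ndarray, power: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Promax rotation: varimax start, then an oblique least-squares fit to
    the element-wise ``|λ|^(power−1)·λ`` target.

    Returns ``(pattern_loadings, factor_correlation)``.  Requires at least
    two factors.
    """
    A = np.asarray(unrotated_loadings, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("promax rotation needs a loading matrix with >= 2 factors")
    # Kaiser-normalized varimax start (the classical convention)
    norms = np.sqrt((A**2).sum(axis=1))
    norms[norms == 0] = 1.0
    V, _ = rotate_factors(A / norms[:, None], "varimax")
    V = V * norms[:, None]
    target = V * np.abs(V) ** (power - 1)
    coef, *_ = np.linalg.lstsq(V, target, rcond=None)
    try:
        coef_norm = np.diag(np.sqrt(np.diag(np.linalg.inv(coef.T @ coef))))
        coef = coef @ coef_norm
        t_inv = np.linalg.inv(coef)
    except np.linalg.LinAlgError as exc:
        raise ValueError("promax transformation matrix is singular") from exc
    pattern = V @ coef
    phi = t_inv @ t_inv.T
    # symmetrize against round-off and renormalize the diagonal
    d = np.sqrt(np.diag(phi))
    phi = (phi + phi.T) / (2.0 * np.outer(d, d))
    return pattern, phi


def efa(item_matrix, n_factors: int | None = None, require_adequacy: bool = False) -> EfaResult:
    """Full exploratory factor analysis: PAF → varimax → promax.

    ``n_factors`` defaults to the Kaiser criterion — the number of
    eigenvalues of the (unreduced) correlation matrix above 1, the scree
    convention of standard statistical packages.  With ``require_adequacy``
    the KMO ≥ 0.6 / Bartlett p < 0.05 gate is enforced before extraction.
    Factors are ordered by variance explained (percentage of total item
    variance in the squared structure loadings) and signed so each factor's
    strongest item loads positively.
    """
    X, items = _as_matrix(item_matrix)
    if require_adequacy:
        overall, _ = kmo(X)
        _, _, p_bart = bartlett_sphericity(X)
        if overall < 0.6 or p_bart >= 0.05:
            raise ValueError(
                f"battery fails the factorability gate (KMO {overall:.3f}, Bartlett p {p_bart:.3g})"
            )
    R = _correlation(X, items)
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    if n_factors is None:
        n_factors = max(int((eigenvalues > 1.0).sum()), 1)
    loadings, communalities = principal_axis_factoring(R, n_factors)
    if n_factors == 1:
        pattern, phi = loadings, np.eye(1)
    else:
        pattern, phi = promax_rotation(loadings)
    structure = pattern @ phi
    var_explained = 100.0 * (structure**2).sum(axis=0) / len(items)
    order = np.argsort(var_explained)[::-1]
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    signs = _column_signs(pattern)
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return EfaResult(
        eigenvalues=eigenvalues,
        pattern_loadings=pattern,
        factor_correlation=phi,
        variance_explained=var_explained[order],
        communalities=communalities,
        n_factors=n_factors,
        heywood=bool(np.any(communalities > 1.0 + 1e-10)),
        items=items,
        factor_names=tuple(f"F{i + 1}" for i in range(n_factors)),
    )


def factor_scores(item_matrix, pattern_loadings: np.ndarray) -> np.ndarray:
    """Weighted-sum factor scores: per subject and factor, Σᵢ λᵢⱼ · xᵢ.

    This is the screening-report convention (loading-weighted sums of raw
    item scores), not regression scoring.
    """
    X, _ = _as_matrix(item_matrix)
    L = np.asarray(pattern_loadings, dtype=float)
    if L.shape[0] != X.shape[1]:
        raise ValueError(
            f"loadings rows ({L.shape[0]}) do not match item count ({X.shape[1]})"
        )
    return X @ L


def reliability(item_matrix) -> ReliabilityResult:
    """Convenience bundle: α, KMO and Bartlett's sphericity for one battery."""
    X, items = _as_matrix(item_matrix)
    overall, per_item = kmo(X)
    chi2, df, p = bartlett_sphericity(X)
    return ReliabilityResult(
        alpha=cronbach_alpha(X),
        kmo_overall=overall,
        kmo_per_item=per_item,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=p,
        n_subjects=X.shape[0],
        items=items,
    )
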