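"""Linear-algebra core of the optimally weighted multi-trait score test.

Given n samples with K quantitative traits Y and M variant dosages X, the
method tests H0: beta = 0 in the linear model

    Y w = beta0 + X beta + eps

for the trait combination ``Y w``.  The score statistic for a fixed weight
vector w is the ratio of quadratic forms

    S(w) = n * w' Y'PX (X'PX)^-1 X'PY w / (w' Y'PY w),

with P the column-centering projector.  Maximizing S(w)/n over w is a
generalized (Rayleigh) eigenproblem: with D = Y'PY = LL' (Cholesky,
optionally ridge-stabilized by lambda0 = 1/n) and
A = Y'PX (X'PX)^-1 X'PY, the maximum T equals the largest eigenvalue of
C = L^-1 A L^-T and is attained at w = L^-T c, where c is the top unit
eigenvector of C.  T lies in [0, 1] because A is D compressed through an
orthogonal projection.  Inference on T is by permutation (see
:mod:`towcm.inference`); T has no usable asymptotic null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import GenotypeMatrix, PhenotypeMatrix

__all__ = [
    "DegenerateTraitError",
    "RankDeficiencyError",
    "ScoreComponents",
    "OptimalWeightSolution",
    "center_columns",
    "drop_collinear_variants",
    "score_components",
    "score_statistic",
    "optimal_weights",
    "tow_cm_statistic",
    "analytic_weight_single_variant",
]

#: relative tolerance for "within tolerance" assertions throughout the core
DEFAULT_TOL = 1e-8

#: relative eigenvalue cutoff below which the trait covariance is treated
#: as singular and the ridge is applied (ridge_policy="auto")
RIDGE_EIG_TOL = 1e-10


class DegenerateTraitError(ValueError):
    """A trait column or trait combination has zero variance."""


class RankDeficiencyError(ValueError):
    """X'PX is singular; carries the offending variant labels."""

    def __init__(self, message: str, variant_ids: list[str] | None = None):
        super().__init__(message)
        self.variant_ids = variant_ids or []


def _matrix(a, what: str) -> np.ndarray:
    """Accept a bare array or a data container exposing ``.values``."""
    if isinstance(a, (PhenotypeMatrix, GenotypeMatrix)):
        a = a.values
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if not np.isfinite(arr).all():
        raise ValueError(f"{what} contains non-finite values")
    return arr


def center_columns(A) -> np.ndarray:
    """Subtract each column's mean: returns PA without materializing P.

    P = I - (1/n) 1 1' is idempotent, so centering twice equals centering
    once, and any constant column maps to zero.
    """
    A = _matrix(A, "input")
    if A.shape[0] < 2:
        raise ValueError("centering requires at least two rows")
    return A - A.mean(axis=0, keepdims=True)


def drop_collinear_variants(
    X, variant_ids: list[str] | None = None, tol: float = 1e-10
) -> tuple[np.ndarray, list[int], list[str]]:
    """Pivoted-QR rank detection on the centered genotype matrix.

    Returns ``(X_kept, kept_indices, dropped_ids)`` where columns are
    dropped when they are (numerically) linear combinations of earlier
    pivots, at relative tolerance ``tol`` on the R diagonal.  Keeping a
    deterministic independent subset preserves the statistic exactly,
    unlike a silent pseudo-inverse.
    """
    X = _matrix(X, "genotype matrix")
    M = X.shape[1]
    ids = variant_ids if variant_ids is not None else [f"v{m + 1}" for m in range(M)]
    Xc = center_columns(X)
    _, R, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int(np.sum(diag > tol * scale))
    if rank == 0:
        raise RankDeficiencyError("all variants are constant after centering", list(ids))
    kept = sorted(piv[:rank].tolist())
    dropped = sorted(set(range(M)) - set(kept))
    return X[:, kept], kept, [ids[j] for j in dropped]


@dataclass
class ScoreComponents:
    """Score vector U, its null variance V, and S = U' V^-1 U."""

    U: np.ndarray
    V: np.ndarray
    S: float


def _cross_products(Y, X):
    """Centered cross-products used by every statistic.

    Returns (Yc, Xc, YtPX, XtPX, D) with D = Y'PY.
    """
    Yc = center_columns(Y)
    Xc = center_columns(X)
    if Yc.shape[0] != Xc.shape[0]:
        raise ValueError("Y and X have different sample counts")
    YtPX = Yc.T @ Xc
    XtPX = Xc.T @ Xc
    D = Yc.T @ Yc
    return Yc, Xc, YtPX, XtPX, D


def _solve_xtx(XtPX: np.ndarray, B: np.ndarray, variant_ids=None) -> np.ndarray:
    """(X'PX)^-1 B via Cholesky; raise RankDeficiencyError when singular."""
    try:
        cf = scipy.linalg.cho_factor(XtPX, lower=True)
    except np.linalg.LinAlgError:
        cf = None
    except scipy.linalg.LinAlgError:  # pragma: no cover - alias of the above
        cf = None
    if cf is None:
        diag = np.sqrt(np.clip(np.diag(XtPX), 1e-300, None))
        ids = variant_ids or [f"v{m + 1}" for m in range(XtPX.shape[0])]
        corr = XtPX / np.outer(diag, diag)
        # name variants involved in (near-)perfect pairwise correlation first
        suspects = sorted(
            {
                ids[i]
                for i in range(len(ids))
                for j in range(len(ids))
                if i != j and abs(corr[i, j]) > 1.0 - 1e-8
            }
        ) or list(ids)
        raise RankDeficiencyError(
            "X'PX is singular (collinear or constant variants); "
            f"suspect variants: {', '.join(suspects)}",
            suspects,
        )
    return scipy.linalg.cho_solve(cf, B)


def score_components(w, Y, X) -> ScoreComponents:
    """Score statistic S = U' V^-1 U for a fixed trait-weight vector w.

    U = (PX)' PYw and V = (1/n) (PYw)'(PYw) (PX)'(PX).  Identical to
    :func:`score_statistic`; both forms are exposed because their
    agreement is a useful correctness check.
    """
    w = np.asarray(w, dtype=float).ravel()
    if not np.any(w != 0):
        raise ValueError("weight vector must not be all zero")
    Yc, Xc, _, XtPX, _ = _cross_products(Y, X)
    n = Yc.shape[0]
    yw = Yc @ w
    denom = float(yw @ yw)
    scale = float(w @ w) * float((Yc**2).sum(axis=0).max())
    if denom <= 0 or denom < DEFAULT_TOL * scale:
        raise DegenerateTraitError("the weighted trait combination Yw is constant")
    U = Xc.T @ yw
    V = (denom / n) * XtPX
    S = float(n * (U @ _solve_xtx(XtPX, U)) / denom)
    return ScoreComponents(U=U, V=V, S=S)


def score_statistic(w, Y, X) -> float:
    """S(w) = n w'Y'PX (X'PX)^-1 X'PY w / (w'Y'PYw); in [0, n]."""
    w = np.asarray(w, dtype=float).ravel()
    if not np.any(w != 0):
        raise ValueError("weight vector must not be all zero")
    Yc, _, YtPX, XtPX, D = _cross_products(Y, X)
    n = Yc.shape[0]
    denom = float(w @ D @ w)
    scale = float(w @ w) * float((Yc**2).sum(axis=0).max())
    if denom <= 0 or denom < DEFAULT_TOL * scale:
        raise DegenerateTraitError("the weighted trait combination Yw is constant")
    b = YtPX.T @ w
    return float(n * (b @ _solve_xtx(XtPX, b)) / denom)


@dataclass
class OptimalWeightSolution:
    """All intermediates of the weight maximization."""

    D: np.ndarray
    ridge_applied: bool
    lambda0: float
    L: np.ndarray
    C: np.ndarray
    c: np.ndarray
    w_opt: np.ndarray
    T: float


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Make the first nonzero component positive (eigenvector sign gauge)."""
    nz = np.nonzero(np.abs(v) > 1e-14)[0]
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def optimal_weights(
    Y,
    X,
    ridge_policy: str = "auto",
    tol: float = RIDGE_EIG_TOL,
    variant_ids: list[str] | None = None,
) -> OptimalWeightSolution:
    """Maximize S(w)/n over trait weights w.

    ridge_policy:
        ``auto``   – add lambda0 I = (1/n) I to D = Y'PY when its Cholesky
                     fails or its smallest eigenvalue is below
                     ``tol``-times its largest (near-collinear traits);
        ``always`` – always add the ridge;
        ``never``  – never add it (raises if D is singular).

    With D = LL', the maximum T of the Rayleigh quotient is the largest
    eigenvalue of C = L^-1 A L^-T, A = Y'PX (X'PX)^-1 X'PY, attained at
    w = L^-T c for the top unit eigenvector c.
    """
    if ridge_policy not in ("auto", "always", "never"):
        raise ValueError(f"unknown ridge_policy {ridge_policy!r}")
    Yc, Xc, YtPX, XtPX, D0 = _cross_products(Y, X)
    n, K = Yc.shape
    if np.all(np.diag(D0) < DEFAULT_TOL * max(1.0, float(np.abs(Yc).max()) ** 2)):
        raise DegenerateTraitError("all trait columns are constant")

    lambda0 = 1.0 / n
    ridge_applied = False
    if ridge_policy == "always":
        ridge_applied = True
    elif ridge_policy == "auto":
        try:
            np.linalg.cholesky(D0)
            eigs = np.linalg.eigvalsh(D0)
            if eigs[0] < tol * eigs[-1]:
                ridge_applied = True
        except np.linalg.LinAlgError:
            ridge_applied = True
    D = D0 + lambda0 * np.eye(K) if ridge_applied else D0

    try:
        L = np.linalg.cholesky(D)
    except np.linalg.LinAlgError as exc:
        raise DegenerateTraitError(
            "trait covariance D is singular; use ridge_policy='auto' or 'always'"
        ) from exc

    half = _solve_xtx(XtPX, YtPX.T, variant_ids)  # (X'PX)^-1 X'PY
    A = YtPX @ half
    Linv_A = scipy.linalg.solve_triangular(L, A, lower=True)
    C = scipy.linalg.solve_triangular(L, Linv_A.T, lower=True).T
    C = 0.5 * (C + C.T)

    evals, evecs = np.linalg.eigh(C)
    T = float(max(evals[-1], 0.0))
    # deterministic tie-break on a (near-)degenerate top eigenvalue
    top = np.nonzero(evals >= evals[-1] - 1e-12)[0]
    candidates = [_sign_fix(evecs[:, j]) for j in top]
    c = max(candidates, key=lambda v: tuple(v))
    w_opt = scipy.linalg.solve_triangular(L, c, lower=True, trans="T")
    return OptimalWeightSolution(
        D=D, ridge_applied=ridge_applied, lambda0=lambda0 if ridge_applied else 0.0,
        L=L, C=C, c=c, w_opt=w_opt, T=T,
    )


def tow_cm_statistic(
    Y, X, ridge_policy: str = "auto"
) -> tuple[float, OptimalWeightSolution]:
    """The TOW-CM statistic T: the maximized score-statistic ratio.

    T = w°' Y'PX (X'PX)^-1 X'PY w° / (w°' D w°) evaluated at the optimal
    weights; the denominator uses the same (possibly ridge-adjusted) D as
    the maximization so that T equals the top eigenvalue of C exactly.
    """
    sol = optimal_weights(Y, X, ridge_policy=ridge_policy)
    _, _, YtPX, XtPX, _ = _cross_products(Y, X)
    b = YtPX.T @ sol.w_opt
    num = float(b @ _solve_xtx(XtPX, b))
    den = float(sol.w_opt @ sol.D @ sol.w_opt)
    T = num / den
    if not np.isclose(T, sol.T, rtol=1e-6, atol=1e-10):  # pragma: no cover
        raise AssertionError(f"ratio form {T} disagrees with eigenvalue {sol.T}")
    return T, sol


def analytic_weight_single_variant(y_k, x) -> float:
    """Closed-form weight for one trait and one variant: x'Py / (y'Py).

    For mutually independent traits and a single variant this is the
    per-trait component of the optimal weight vector; its sign follows
    the sample covariance of x and y.
    """
    y = np.asarray(y_k, dtype=float).ravel()
    xv = np.asarray(x, dtype=float).ravel()
    if y.shape != xv.shape:
        raise ValueError("y and x must have equal length")
    yc = y - y.mean()
    xc = xv - xv.mean()
    den = float(yc @ yc)
    if den <= 0:
        raise DegenerateTraitError("trait is constant")
    return float(xc @ yc) / den
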