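"""Low-rank thin-plate regression spline (TPRS) bases.

A smooth f(x) is represented in the classical thin-plate spline form

    f(x) = sum_j delta_j eta(||x - knot_j||) + polynomial(x),

subject to the orthogonality constraint T' delta = 0, where the polynomial
part spans the penalty null space (constant + linear terms).  The full-rank
system on knots at the (unique) data values is reduced to its ``k`` leading
eigenvectors, which preserves as much of the flexible part of the basis as
possible for a given dimension.  A sum-to-zero constraint (column
centering against the training data) makes the smooth identifiable next to
a free intercept, leaving ``k - 1`` design columns per term.

The wiggliness penalty is exactly zero for any linear function of the
covariate(s): the penalty matrix has rank ``k - null_space_dim``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from zicpue.errors import BasisError

__all__ = ["SmoothBasis", "build_tprs_basis", "build_tprs_basis_2d", "evaluate_smooth"]

# cap on the number of knots used for the eigen-reduction; above this the
# unique covariate values are thinned to evenly spaced quantiles
MAX_KNOTS = 500


def _eta_1d(r: np.ndarray) -> np.ndarray:
    # radial Green's function for d=1, m=2 (cubic smoothing spline energy)
    return r**3 / 12.0


def _eta_2d(r: np.ndarray) -> np.ndarray:
    # d=2, m=2 thin-plate kernel; eta(0) = 0
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = (r[pos] ** 2) * np.log(r[pos]) / (8.0 * np.pi)
    return out


@dataclass
class SmoothBasis:
    """A constructed low-rank thin-plate regression spline basis.

    ``design`` maps covariate values to the (k-1)-column model-matrix
    block: ``k - null_space_dim`` penalized columns followed by the
    centered linear column(s).  ``penalty`` is the matching symmetric PSD
    penalty matrix, zero on the linear columns.
    """

    names: tuple[str, ...]
    k: int
    null_space_dim: int
    penalty: np.ndarray
    knots: np.ndarray  # (K, d) standardized coordinates
    _map: np.ndarray = field(repr=False)  # (K, k - M): U_k @ Z
    col_means: np.ndarray = field(repr=False)
    center: np.ndarray = field(repr=False)  # coordinate centering (d,)
    scale: np.ndarray = field(repr=False)  # coordinate scaling (d,)
    x_min: np.ndarray = field(repr=False)
    x_max: np.ndarray = field(repr=False)

    @property
    def n_cols(self) -> int:
        return self.k - 1

    @property
    def dim(self) -> int:
        return self.knots.shape[1]

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dim:
            x = x.T
        if x.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim} coordinate column(s)")
        return (x - self.center) / self.scale

    def design(self, *coords: np.ndarray) -> np.ndarray:
        """Model-matrix block for new covariate values (centered columns)."""
        x = np.column_stack([np.asarray(c, dtype=float).ravel() for c in coords])
        z = self._standardize(x)
        eta = _eta_1d if self.dim == 1 else _eta_2d
        A = eta(cdist(z, self.knots))
        smooth_cols = A @ self._map
        linear_cols = z  # all d coordinates; constant absorbed by intercept
        X = np.hstack([smooth_cols, linear_cols])
        return X - self.col_means

    def extrapolation_mask(self, *coords: np.ndarray) -> np.ndarray:
        x = np.column_stack([np.asarray(c, dtype=float).ravel() for c in coords])
        return ((x < self.x_min) | (x > self.x_max)).any(axis=1)


def _build(x: np.ndarray, k: int, null_dim: int, eta) -> SmoothBasis:
    n, d = x.shape
    center = x.mean(axis=0)
    if d == 1:
        scale = np.ones(1)
    else:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        scale = sd
    z = (x - center) / scale

    knots = np.unique(z, axis=0)
    if knots.shape[0] > MAX_KNOTS:
        # deterministic quantile thinning on the first coordinate ordering
        idx = np.linspace(0, knots.shape[0] - 1, MAX_KNOTS).round().astype(int)
        order = np.lexsort(knots.T[::-1])
        knots = knots[order][np.unique(idx)]
    K = knots.shape[0]
    if K < k:
        raise BasisError(
            f"basis dimension k={k} requires at least k distinct covariate "
            f"values, got {K}"
        )

    E = eta(cdist(knots, knots))
    T = np.hstack([np.ones((K, 1)), knots])  # (K, null_dim)
    if null_dim != T.shape[1]:  # pragma: no cover - construction invariant
        raise BasisError("null space dimension mismatch")

    evals, evecs = np.linalg.eigh(E)
    top = np.argsort(np.abs(evals))[::-1][:k]
    D_k = evals[top]
    U_k = evecs[:, top]

    # absorb T' delta = 0: basis for null(T' U_k)
    C = T.T @ U_k  # (M, k)
    _, s, Vt = np.linalg.svd(C, full_matrices=True)
    rank_c = int((s > s.max() * 1e-10).sum()) if s.size else 0
    Z = Vt[rank_c:].T  # (k, k - rank_c)
    if Z.shape[1] != k - null_dim:
        warnings.warn(
            "degenerate covariate configuration: constraint matrix is rank "
            "deficient; basis returned with reduced penalized dimension",
            RuntimeWarning,
        )

    mapping = U_k @ Z  # (K, k - M)
    S_z = Z.T @ (D_k[:, None] * Z)
    S_z = 0.5 * (S_z + S_z.T)
    # clip negligible negative eigenvalues from truncation noise
    w, V = np.linalg.eigh(S_z)
    w = np.clip(w, 0.0, None)
    S_z = V @ (w[:, None] * V.T)
    S_z = 0.5 * (S_z + S_z.T)

    n_smooth = mapping.shape[1]
    n_linear = d
    p = n_smooth + n_linear
    penalty = np.zeros((p, p))
    penalty[:n_smooth, :n_smooth] = S_z

    basis = SmoothBasis(
        names=(),
        k=k,
        null_space_dim=null_dim,
        penalty=penalty,
        knots=knots,
        _map=mapping,
        col_means=np.zeros(p),
        center=center,
        scale=scale,
        x_min=x.min(axis=0),
        x_max=x.max(axis=0),
    )
    # centering constraint: columns sum to zero over the training data
    raw = basis.design(*(x[:, j] for j in range(d)))
    basis.col_means = raw.mean(axis=0)
    return basis


def build_tprs_basis(x: np.ndarray, k: int, name: str = "x") -> SmoothBasis:
    """One-dimensional thin-plate regression spline basis of dimension k.

    Knots sit at the unique data values (thinned to quantiles when very
    numerous).  The penalty null space contains constants and linear
    functions; the constant is removed by the centering constraint, so the
    returned block has ``k - 1`` columns and penalty rank ``k - 2``.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if k < 3:
        raise BasisError(f"k must be >= 3 for a 1-D smooth, got {k}")
    basis = _build(x, k, null_dim=2, eta=_eta_1d)
    basis.names = (name,)
    return basis


def build_tprs_basis_2d(
    x1: np.ndarray, x2: np.ndarray, k: int, names: tuple[str, str] = ("x1", "x2")
) -> SmoothBasis:
    """Isotropic 2-D thin-plate regression spline on standardized coordinates.

    Both coordinates are scaled to unit standard deviation before distances
    are computed, so covariates on very different scales (e.g. year and
    month) contribute comparably to the bending energy.  The penalty null
    space spans {1, x1, x2}.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if k < 4:
        raise BasisError(f"k must be >= 4 for a 2-D smooth, got {k}")
    if x1.shape != x2.shape:
        raise BasisError("x1 and x2 must have the same length")
    x = np.column_stack([x1, x2])
    if k > x.shape[0]:
        raise BasisError(f"k={k} exceeds the number of observations {x.shape[0]}")
    rank_xy = np.linalg.matrix_rank(x - x.mean(axis=0))
    if rank_xy < 2:
        warnings.warn(
            "all points are collinear: 2-D basis is rank deficient",
            RuntimeWarning,
        )
    basis = _build(x, k, null_dim=3, eta=_eta_2d)
    basis.names = tuple(names)
    return basis


@dataclass
class EvaluatedSmooth:
    """Values of a fitted smooth on a grid, with an extrapolation flag."""

    values: np.ndarray
    extrapolated: np.ndarray

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def evaluate_smooth(basis: SmoothBasis, coefs: np.ndarray, *coords) -> EvaluatedSmooth:
    """Evaluate a smooth term at new covariate values.

    ``coefs`` has length ``k - 1`` (the post-constraint dimension).  Points
    outside the training range are evaluated (the basis extends smoothly)
    but flagged as extrapolation.
    """
    coefs = np.asarray(coefs, dtype=float).ravel()
    if coefs.size != basis.n_cols:
        raise ValueError(
            f"expected {basis.n_cols} coefficients for k={basis.k}, got {coefs.size}"
        )
    X = basis.design(*coords)
    return EvaluatedSmooth(
        values=X @ coefs, extrapolated=basis.extrapolation_mask(*coords)
    )
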