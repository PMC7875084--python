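"""Wishart density, SPD validation, and Wishart sampling.

The Wishart distribution :math:`W_p(n, \\Sigma)` is the law of
:math:`M = \\sum_{i=1}^{n} X_i X_i'` for i.i.d. mean-zero Gaussian
p-vectors :math:`X_i \\sim N_p(0, \\Sigma)`. Its density on the cone of
symmetric positive-definite (SPD) matrices, for :math:`n \\ge p` and
invertible scale :math:`\\Sigma`, is

.. math::

    f(M, n, \\Sigma) = \\frac{|M|^{(n-p-1)/2}
        \\exp[-\\tfrac12 \\mathrm{tr}(\\Sigma^{-1} M)]}
        {2^{np/2}\\, \\Gamma_p(n/2)\\, |\\Sigma|^{n/2}}

and zero elsewhere. Everything here is computed in log space:
the normalizing constant underflows catastrophically at the matrix
sizes this package targets (e.g. p = 116 brain parcels, n = 200
time points), while the log-density stays perfectly representable.

Log-determinants come from Cholesky factor diagonals and the trace
term from a triangular solve, so no explicit inverse or determinant
is ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import gammaln

from .exceptions import (
    AsymmetricError,
    DegreesOfFreedomError,
    DimensionMismatchError,
    DomainError,
    NonSquareError,
    NotPositiveDefiniteError,
    SingularScaleError,
)

__all__ = [
    "SPDMatrix",
    "WishartParams",
    "validate_spd",
    "log_multivariate_gamma",
    "wishart_log_pdf",
    "sample_wishart",
]

#: Default relative tolerance for the symmetry check.
DEFAULT_SYM_TOL = 1e-8
#: Default relative tolerance on squared Cholesky diagonals (vs. max diagonal).
DEFAULT_PD_TOL = 1e-10


@dataclass(frozen=True)
class SPDMatrix:
    """A validated symmetric positive-definite matrix.

    Instances are produced by :func:`validate_spd`; ``values`` holds the
    symmetrized matrix and ``chol`` caches its lower Cholesky factor so
    downstream density evaluations never re-factorize.

    Attributes
    ----------
    values : ndarray, shape (p, p)
        Symmetrized matrix.
    p : int
        Dimension.
    is_correlation : bool
        True when every diagonal entry is 1 (within the symmetry
        tolerance used at validation time).
    chol : ndarray, shape (p, p)
        Lower-triangular Cholesky factor, ``chol @ chol.T == values``.
    """

    values: np.ndarray
    p: int
    is_correlation: bool
    chol: np.ndarray = field(repr=False)

    @property
    def log_det(self) -> float:
        """Log-determinant from the Cholesky diagonal."""
        return 2.0 * float(np.sum(np.log(np.diag(self.chol))))


@dataclass(frozen=True)
class WishartParams:
    """Parameters (scale matrix, degrees of freedom) of a Wishart law.

    ``dof`` must be an integer at least the dimension ``scale.p``: below
    that the scale-consistent density does not exist (the p > n regime),
    which is the method's hard applicability limit.
    """

    scale: SPDMatrix
    dof: int

    def __post_init__(self) -> None:
        if not float(self.dof).is_integer():
            raise DegreesOfFreedomError(
                f"degrees of freedom must be an integer, got {self.dof!r}"
            )
        object.__setattr__(self, "dof", int(self.dof))
        if self.dof < self.scale.p:
            raise DegreesOfFreedomError(
                f"dof={self.dof} < p={self.scale.p}: density undefined when "
                "the number of features exceeds the sampling"
            )

    @classmethod
    def from_arrays(
        cls,
        scale: np.ndarray,
        dof: int,
        ridge: float = 0.0,
        sym_tol: float = DEFAULT_SYM_TOL,
        pd_tol: float = DEFAULT_PD_TOL,
    ) -> "WishartParams":
        """Build params from a raw scale array, raising
        :class:`SingularScaleError` when the scale has no triangular
        factorization (optionally after a ``ridge * I`` shift)."""
        try:
            spd = validate_spd(scale, sym_tol=sym_tol, pd_tol=pd_tol, ridge=ridge)
        except (NotPositiveDefiniteError, AsymmetricError) as exc:
            raise SingularScaleError(f"scale matrix is not usable: {exc}") from exc
        return cls(scale=spd, dof=dof)


def validate_spd(
    values: np.ndarray,
    sym_tol: float = DEFAULT_SYM_TOL,
    pd_tol: float = DEFAULT_PD_TOL,
    ridge: float = 0.0,
) -> SPDMatrix:
    """Validate a matrix as SPD and return the canonical representation.

    Parameters
    ----------
    values : array_like, shape (p, p)
        Square real matrix.
    sym_tol : float
        Relative symmetry tolerance: require
        ``max|A - A'| <= sym_tol * max|A|``. Asymmetry within tolerance
        is repaired by storing ``(A + A') / 2``.
    pd_tol : float
        Relative positive-definiteness tolerance: every squared Cholesky
        diagonal must exceed ``pd_tol * max(diag(A))``.
    ridge : float
        Optional diagonal shift ``ridge * I`` applied before
        factorization, for near-singular matrices (default 0: the
        matrix is taken exactly as supplied).

    Raises
    ------
    NonSquareError, AsymmetricError, NotPositiveDefiniteError
    """
    a = np.asarray(values, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise NonSquareError(f"expected a square matrix, got shape {a.shape}")
    if a.size == 0:
        raise NonSquareError("empty matrix")

    scale = np.max(np.abs(a))
    asym = np.max(np.abs(a - a.T))
    if asym > sym_tol * max(scale, 1.0):
        raise AsymmetricError(
            f"asymmetry {asym:.3g} exceeds tolerance {sym_tol:.3g} * {scale:.3g}"
        )
    sym = (a + a.T) / 2.0
    if ridge:
        sym = sym + ridge * np.eye(sym.shape[0])

    try:
        chol = np.linalg.cholesky(sym)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(f"Cholesky factorization failed: {exc}") from exc
    diag2 = np.diag(chol) ** 2
    floor = pd_tol * max(np.max(np.diag(sym)), 0.0)
    if np.any(diag2 <= floor):
        raise NotPositiveDefiniteError(
            f"matrix numerically singular: min squared pivot {diag2.min():.3g} "
            f"<= {floor:.3g}"
        )

    p = sym.shape[0]
    is_corr = bool(np.all(np.abs(np.diag(sym) - 1.0) <= sym_tol))
    return SPDMatrix(values=sym, p=p, is_correlation=is_corr, chol=chol)


def is_spd(values: np.ndarray, sym_tol: float = DEFAULT_SYM_TOL,
           pd_tol: float = DEFAULT_PD_TOL) -> bool:
    """True when :func:`validate_spd` would accept ``values``."""
    try:
        validate_spd(values, sym_tol=sym_tol, pd_tol=pd_tol)
    except (NonSquareError, AsymmetricError, NotPositiveDefiniteError):
        return False
    return True


def log_multivariate_gamma(p: int, a: float) -> float:
    """Log of the multivariate (generalized) gamma function.

    .. math::

        \\log \\Gamma_p(a) = \\frac{p(p-1)}{4} \\log \\pi
            + \\sum_{i=1}^{p} \\log \\Gamma\\!\\left(\\frac{2a + 1 - i}{2}\\right)

    Requires every univariate gamma argument positive, i.e.
    ``2a + 1 - p > 0``.
    """
    if p < 1 or not float(p).is_integer():
        raise DomainError(f"dimension p must be a positive integer, got {p!r}")
    p = int(p)
    if 2.0 * a + 1.0 - p <= 0.0:
        raise DomainError(
            f"log_multivariate_gamma undefined: 2a+1-p = {2 * a + 1 - p:.3g} <= 0"
        )
    i = np.arange(1, p + 1)
    return float(p * (p - 1) / 4.0 * np.log(np.pi) + np.sum(gammaln((2.0 * a + 1.0 - i) / 2.0)))


def wishart_log_pdf(
    M: SPDMatrix | np.ndarray,
    params: WishartParams,
    sym_tol: float = DEFAULT_SYM_TOL,
    pd_tol: float = DEFAULT_PD_TOL,
) -> float:
    """Log density of ``M`` under ``W_p(params.dof, params.scale)``.

    Returns ``-inf`` (not an error) when ``M`` is not symmetric
    positive-definite, mirroring the density being identically zero off
    the SPD cone. Raw arrays are validated on the fly; pre-validated
    :class:`SPDMatrix` inputs reuse their cached Cholesky factor.

    Raises
    ------
    DimensionMismatchError
        Dimension of ``M`` differs from the scale matrix.
    SingularScaleError
        Is raised earlier, by scale validation; here the triangular
        solve against the cached factor cannot fail for a valid scale.
    """
    sigma = params.scale
    n = params.dof
    p = sigma.p

    if not isinstance(M, SPDMatrix):
        arr = np.asarray(M, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise DimensionMismatchError(
                f"matrix shape {arr.shape} incompatible with p={p}"
            )
        if arr.shape[0] != p:
            raise DimensionMismatchError(f"matrix is {arr.shape[0]}x{arr.shape[0]}, scale is {p}x{p}")
        try:
            M = validate_spd(arr, sym_tol=sym_tol, pd_tol=pd_tol)
        except (AsymmetricError, NotPositiveDefiniteError):
            return -np.inf
    elif M.p != p:
        raise DimensionMismatchError(f"matrix is {M.p}x{M.p}, scale is {p}x{p}")

    # tr(Sigma^-1 M) via two triangular solves against the cached factor L:
    # Sigma = L L'  =>  tr(Sigma^-1 M) = ||L^-1 B||_F^2 with M = B B'.
    y = linalg.solve_triangular(sigma.chol, M.chol, lower=True, check_finite=False)
    trace_term = float(np.sum(y * y))

    return (
        -(n * p / 2.0) * np.log(2.0)
        - log_multivariate_gamma(p, n / 2.0)
        - (n / 2.0) * sigma.log_det
        + ((n - p - 1) / 2.0) * M.log_det
        - 0.5 * trace_term
    )


def sample_wishart(
    params: WishartParams,
    n_draws: int,
    seed: int | np.random.Generator,
) -> list[SPDMatrix]:
    """Draw ``n_draws`` matrices from ``W_p(params.dof, params.scale)``.

    Uses the defining construction: with ``A`` the lower-triangular
    factor of the scale (``A A' = Sigma``) and ``Z_i`` i.i.d. standard
    normal p-vectors, each draw is ``A (sum_i Z_i Z_i') A'``. The seed
    is mandatory; there is no global random state.
    """
    if n_draws < 0:
        raise DomainError(f"n_draws must be non-negative, got {n_draws}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = params.scale.chol  # raises at validate_spd time if no factor exists
    p, n = params.scale.p, params.dof

    draws: list[SPDMatrix] = []
    for _ in range(n_draws):
        z = rng.standard_normal((p, n))
        az = a @ z
        m = az @ az.T
        draws.append(validate_spd(m))
    return draws
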