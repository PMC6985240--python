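"""Second-order polynomial viability surface: fitting and prediction.

The model is

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j

where ``x_i`` is the regression-scale coded dose of drug i (vehicle at the
origin, non-zero levels on [-1, +1]; see :func:`qpop.panel.coded_value`).
Fitting is ordinary least squares by default, with an optional ridge
penalty (intercept excluded) as a guarded fallback for rank-deficient
user-supplied designs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimabilityError, ValidationError
from .panel import DesignTable, DoseVector, DrugPanel, coded_value

__all__ = [
    "QuadraticSurface",
    "fit_surface",
    "predict_viability",
    "evaluate_coded",
    "quadratic_model_matrix",
    "term_names",
]


def term_names(panel: DrugPanel) -> list[str]:
    """Labels for the coefficient vector, in model-matrix column order."""
    names = ["b0"]
    names += [f"b:{d}" for d in panel.names]
    names += [f"b2:{d}" for d in panel.names]
    names += [f"b:{a}:{b}" for a, b in itertools.combinations(panel.names, 2)]
    return names


def _coded_matrix(levels: np.ndarray, L: int) -> np.ndarray:
    lut = np.array([coded_value(lv, L) for lv in range(L + 1)])
    return lut[np.asarray(levels, dtype=int)]


def quadratic_model_matrix(levels: np.ndarray, L: int) -> np.ndarray:
    """Design matrix of the full quadratic model for coded-level rows."""
    X = _coded_matrix(np.atleast_2d(levels), L)
    return _model_matrix_from_coded(X)


def _model_matrix_from_coded(X: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    cols = [np.ones(X.shape[0]), *(X[:, i] for i in range(n))]
    cols += [X[:, i] ** 2 for i in range(n)]
    cols += [X[:, i] * X[:, j] for i, j in itertools.combinations(range(n), 2)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class QuadraticSurface:
    """Fitted (or ground-truth) quadratic viability surface."""

    panel: DrugPanel
    beta0: float
    beta_lin: np.ndarray  # (n,)
    beta_quad: np.ndarray  # (n,)
    beta_int: np.ndarray  # (C(n,2),) in lexicographic i<j order
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        n = self.panel.n
        object.__setattr__(self, "beta_lin", np.asarray(self.beta_lin, dtype=float))
        object.__setattr__(self, "beta_quad", np.asarray(self.beta_quad, dtype=float))
        object.__setattr__(self, "beta_int", np.asarray(self.beta_int, dtype=float))
        if self.beta_lin.shape != (n,) or self.beta_quad.shape != (n,):
            raise ValidationError("linear/quadratic coefficient vectors must have length n")
        if self.beta_int.shape != (n * (n - 1) // 2,):
            raise ValidationError(
                f"interaction vector must have length C(n,2) = {n * (n - 1) // 2}"
            )
        coefs = self.coefficients
        if not np.all(np.isfinite(coefs)):
            raise ValidationError("non-finite surface coefficient")

    @property
    def coefficients(self) -> np.ndarray:
        """Full coefficient vector in model-matrix column order."""
        return np.concatenate(
            [[self.beta0], self.beta_lin, self.beta_quad, self.beta_int]
        )

    @classmethod
    def from_coefficients(
        cls, panel: DrugPanel, coefs: np.ndarray, diagnostics: dict | None = None
    ) -> "QuadraticSurface":
        coefs = np.asarray(coefs, dtype=float)
        n = panel.n
        expected = 1 + 2 * n + n * (n - 1) // 2
        if coefs.shape != (expected,):
            raise ValidationError(
                f"expected {expected} coefficients for n={n}, got {coefs.size}"
            )
        return cls(
            panel=panel,
            beta0=float(coefs[0]),
            beta_lin=coefs[1 : 1 + n],
            beta_quad=coefs[1 + n : 1 + 2 * n],
            beta_int=coefs[1 + 2 * n :],
            diagnostics=diagnostics or {},
        )

    def interaction(self, name_a: str, name_b: str) -> float:
        """Pairwise interaction coefficient for two named drugs."""
        i, j = self.panel.index_of(name_a), self.panel.index_of(name_b)
        if i == j:
            raise ValidationError("interaction requires two distinct drugs")
        i, j = min(i, j), max(i, j)
        pairs = list(itertools.combinations(range(self.panel.n), 2))
        return float(self.beta_int[pairs.index((i, j))])


def fit_surface(design: DesignTable, regularization: float = 0.0) -> QuadraticSurface:
    """Least-squares fit of the quadratic surface to design readouts.

    With ``regularization`` 0 (default) this is OLS and the design must be
    estimable; a positive value adds a ridge penalty on every term except
    the intercept.  Diagnostics include R^2, residual SD, the model-matrix
    condition number and leave-one-out cross-validation RMSE.
    """
    if design.viability is None:
        raise ValidationError("design has no viability readouts to fit")
    if regularization < 0:
        raise ValidationError("regularization must be non-negative")
    y = design.viability
    M = quadratic_model_matrix(design.runs, design.panel.L)
    n_terms = M.shape[1]

    if design.n_runs < n_terms:
        warnings.warn(
            f"{design.n_runs} runs for {n_terms} coefficients: fit is underdetermined",
            stacklevel=2,
        )

    rank = int(np.linalg.matrix_rank(M))
    if regularization == 0.0 and rank < n_terms:
        from .panel import validate_design

        diag = validate_design(design)
        raise EstimabilityError(
            f"design is rank-deficient (rank {rank} < {n_terms}); "
            f"confounded terms: {diag.confounded_terms}; "
            "supply a richer design or a positive regularization"
        )

    if regularization == 0.0:
        coefs, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        # hat diagonal via economy QR for LOO residuals
        Q, _ = np.linalg.qr(M)
        hat = np.sum(Q**2, axis=1)
    else:
        P = np.eye(n_terms)
        P[0, 0] = 0.0  # intercept unpenalized
        A = M.T @ M + regularization * P
        coefs = np.linalg.solve(A, M.T @ y)
        S = M @ np.linalg.solve(A, M.T)
        hat = np.diag(S)

    resid = y - M @ coefs
    dof = max(design.n_runs - rank, 1)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = resid / np.where(1.0 - hat > 1e-12, 1.0 - hat, np.nan)
    diagnostics = {
        "r_squared": 1.0 - rss / tss if tss > 0 else 1.0,
        "residual_sd": float(np.sqrt(rss / dof)),
        "condition_number": float(np.linalg.cond(M)),
        "loo_rmse": float(np.sqrt(np.nanmean(loo**2))),
        "n_runs": design.n_runs,
        "rank": rank,
        "regularization": regularization,
    }
    return QuadraticSurface.from_coefficients(design.panel, coefs, diagnostics)


def evaluate_coded(surface: QuadraticSurface, x: np.ndarray) -> float | np.ndarray:
    """Evaluate the surface at regression-scale coded values.

    ``x`` may be a single length-n vector or an (m, n) batch; values off the
    [-1, 1] hull are permitted (extrapolation for response-surface maps).
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != surface.panel.n:
        raise ValidationError(
            f"coded vector length {X.shape[1]} != panel size {surface.panel.n}"
        )
    out = _model_matrix_from_coded(X) @ surface.coefficients
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def predict_viability(surface: QuadraticSurface, dv: DoseVector) -> float:
    """Predicted viability at an on-grid coded dose vector.

    The all-vehicle vector returns ``beta0`` exactly (coded origin).
    """
    dv.validate(surface.panel)
    x = np.array([coded_value(lv, surface.panel.L) for lv in dv.levels])
    return float(evaluate_coded(surface, x))


def predict_many(surface: QuadraticSurface, levels: np.ndarray) -> np.ndarray:
    """Vectorized :func:`predict_viability` over a matrix of coded levels."""
    levels = np.asarray(levels, dtype=int)
    if levels.ndim != 2 or levels.shape[1] != surface.panel.n:
        raise ValidationError("levels must be an (m, n) matrix matching the panel")
    if levels.min() < 0 or levels.max() > surface.panel.L:
        raise ValidationError("coded level outside panel grid")
    M = quadratic_model_matrix(levels, surface.panel.L)
    return M @ surface.coefficients
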