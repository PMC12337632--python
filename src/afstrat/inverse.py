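"""Zero-order Tikhonov inversion of body-surface potentials.

The inverse problem Y = T X is ill-posed: the forward operator smooths
high-spatial-frequency source detail, so naive least squares amplifies
measurement noise. Zero-order Tikhonov regularization minimises
``||T X - Y||^2 + lambda^2 ||X||^2`` columnwise, damping small singular
components with filter factors ``s^2 / (s^2 + lambda^2)``.

One SVD of T is reused for all candidate lambdas, and the regularization
weight for a recording window is picked once on the window's stacked
columns at the L-curve's maximum-curvature point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signals import NodeSignalSet
from .synthetic import TransferMatrix

__all__ = ["RegularizedSolution", "tikhonov_solve", "choose_lambda"]

_RANK_RTOL = 1e-12  # relative singular-value truncation at lambda = 0


@dataclass
class RegularizedSolution:
    """One regularized solve: reconstructed sources and its norms."""

    sources: np.ndarray  # (n_sources, n_samples) icEGMs
    lam: float
    residual_norm: float  # ||T X - Y||_F
    solution_norm: float  # ||X||_F

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not (np.isfinite(self.residual_norm) and np.isfinite(self.solution_norm)):
            raise ValueError("norms must be finite")

    def as_signalset(self, fs_hz: float, source_positions=None) -> NodeSignalSet:
        return NodeSignalSet(
            samples=self.sources,
            fs_hz=fs_hz,
            role="icegm",
            channel_positions=source_positions,
            meta={"lambda": self.lam},
        )


def _svd(T: np.ndarray):
    return np.linalg.svd(T, full_matrices=False)


def tikhonov_solve(
    T: TransferMatrix | np.ndarray,
    surface: NodeSignalSet | np.ndarray,
    lam: float,
    svd=None,
) -> RegularizedSolution:
    """Solve ``argmin ||T X - Y||^2 + lam^2 ||X||^2`` columnwise via SVD.

    For ``lam = 0`` this is the minimum-norm least-squares solution with
    relative rank truncation at 1e-12. Pass a precomputed ``svd=(U, s, Vt)``
    to amortise the decomposition over many lambdas.
    """
    A = T.entries if isinstance(T, TransferMatrix) else np.asarray(T, dtype=float)
    Y = surface.samples if isinstance(surface, NodeSignalSet) else np.atleast_2d(
        np.asarray(surface, dtype=float)
    )
    if Y.ndim == 1:
        Y = Y[:, None]
    if not np.all(np.isfinite(A)) or not np.all(np.isfinite(Y)):
        raise ValueError("NaN or inf in inputs")
    if A.shape[0] != Y.shape[0]:
        raise ValueError(f"shape mismatch: T has {A.shape[0]} rows, Y has {Y.shape[0]}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    U, s, Vt = svd if svd is not None else _svd(A)
    beta = U.T @ Y  # coefficients in the left singular basis
    if lam == 0.0:
        keep = s > _RANK_RTOL * s[0]
        f_over_s = np.zeros_like(s)
        f_over_s[keep] = 1.0 / s[keep]
    else:
        f_over_s = s / (s**2 + lam**2)
    X = Vt.T @ (f_over_s[:, None] * beta)
    residual = float(np.linalg.norm(A @ X - Y))
    return RegularizedSolution(
        sources=X, lam=float(lam), residual_norm=residual,
        solution_norm=float(np.linalg.norm(X)),
    )


def choose_lambda(
    T: TransferMatrix | np.ndarray,
    surface: NodeSignalSet | np.ndarray,
    grid: np.ndarray,
) -> float:
    """Pick the regularization weight at the L-curve corner.

    The L-curve plots log residual norm against log solution norm over the
    lambda grid; the corner (maximum curvature of the parametric curve) is
    the classical compromise between data fit and solution energy. A flat
    curve (degenerate problem) triggers a warning and returns the grid
    median. Deterministic for a fixed grid.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if grid.size == 1:
        return float(grid[0])

    A = T.entries if isinstance(T, TransferMatrix) else np.asarray(T, dtype=float)
    svd = _svd(A)
    rho = np.empty(grid.size)
    eta = np.empty(grid.size)
    for i, lam in enumerate(grid):
        sol = tikhonov_solve(A, surface, lam, svd=svd)
        rho[i], eta[i] = sol.residual_norm, sol.solution_norm

    Y = surface.samples if isinstance(surface, NodeSignalSet) else np.atleast_2d(
        np.asarray(surface, dtype=float)
    )
    y_norm = float(np.linalg.norm(Y))
    # consistent data: no regularization needed, corner degenerates to the
    # smallest grid value
    if rho[0] <= 1e-10 * max(y_norm, 1.0):
        return float(grid[0])

    tiny = np.finfo(float).tiny
    x = np.log(np.maximum(rho, tiny))
    y = np.log(np.maximum(eta, tiny))
    if np.ptp(x) < 1e-9 and np.ptp(y) < 1e-9:
        warnings.warn("flat L-curve; returning grid median", stacklevel=2)
        return float(grid[grid.size // 2])

    # curvature of the parametric curve (x(lam), y(lam))
    u = np.log(grid)
    dx, dy = np.gradient(x, u), np.gradient(y, u)
    ddx, ddy = np.gradient(dx, u), np.gradient(dy, u)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, (dx * ddy - dy * ddx) / np.maximum(denom, tiny), -np.inf)
    kappa[~np.isfinite(kappa)] = -np.inf
    # flat stretches of the curve (speed ~ 0, e.g. lambda far below the
    # smallest singular value) carry only numerical curvature noise, and the
    # corner must sit where the residual actually responds to lambda —
    # dx ~ 0 marks the vertical limb, whose upper bend is not the corner
    speed = np.hypot(dx, dy)
    kappa[speed < max(1e-6, 0.01 * speed.max())] = -np.inf
    if dx.max() > 0:
        kappa[dx < 0.02 * dx.max()] = -np.inf
    if not np.any(np.isfinite(kappa)):
        warnings.warn("degenerate L-curve curvature; returning grid median", stacklevel=2)
        return float(grid[grid.size // 2])
    return float(grid[int(np.argmax(kappa))])
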