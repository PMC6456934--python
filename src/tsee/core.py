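"""Time-series elastic embedding: energy, gradient and optimizer.

The embedding minimizes, over low-dimensional coordinates X (N x d),

    E[X; lambda, beta] = sum_{n!=m} w^P_nm ||x_n - x_m||^2
                       + lambda * sum_{n!=m} (w^N_nm + beta * t_nm)
                                  * exp(-||x_n - x_m||^2)

where the attractive weights w^P are normalized Gaussian affinities of the
input expression profiles, the repulsive weights w^N are normalized input
Euclidean distances, and t_nm are normalized experimental time intervals
|t(n) - t(m)| (or any caller-supplied symmetric side distance, e.g. a
1 - PCC spatial distance over marker genes). Both sums run over ordered
pairs n != m; the gradient 4 L X below uses the same convention.

With beta = 0 the energy is exactly elastic embedding (EE); with lambda = 0
only the attractive quadratic term remains (the Laplacian-eigenmap limit).

Minimization follows the partial-Hessian spectral-direction scheme: the
search direction solves (L^P (x) I_d + mu I) p = -g, where L^P is the graph
Laplacian of the attractive weights — the convex part of the Hessian — so p
is always a descent direction; steps are chosen by Armijo backtracking.
Because the Kronecker structure decouples over embedding columns, one
Cholesky factorization of (L^P + mu I) per fit serves every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .dataset import TimeSeriesDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityModel",
    "EmbeddingConfig",
    "EmbeddingResult",
    "OptimizerState",
    "pairwise_sq_distances",
    "build_affinities",
    "tsee_energy",
    "combined_laplacian",
    "tsee_gradient",
    "attractive_laplacian_factor",
    "spectral_direction",
    "armijo_step",
    "fit_tsee",
    "resolve_sigma",
]

_SIZE_WARN_THRESHOLD = 10_000


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AffinityModel:
    """Normalized weight matrices of the embedding energy, bound to (beta, sigma).

    ``w_plus`` holds the attractive weights w^P (off-diagonal sum exactly 1),
    ``w_minus`` the normalized disparity weights w^N, and ``t_side`` the
    normalized side/time weights t; w^N and t share the normalizer
    N^- = 1 / sum(w^- + beta * side), so sum(w_minus + beta * t_side) = 1.
    """

    w_plus: np.ndarray
    w_minus: np.ndarray
    t_side: np.ndarray
    beta: float
    sigma: float

    @property
    def n_cells(self) -> int:
        return self.w_plus.shape[0]

    def repulsive_weights(self) -> np.ndarray:
        """The combined repulsive weight matrix w^N + beta * t."""
        return self.w_minus + self.beta * self.t_side


@dataclass
class EmbeddingConfig:
    """Tunable parameters of the embedding.

    lam trades attractive vs repulsive forces; beta weights the temporal
    (side-information) repulsion relative to the expression disparity. Both
    default to 10. sigma_policy is "median_distance" (median off-diagonal
    pairwise Euclidean input distance) or "fixed:<value>".
    """

    lam: float = 10.0
    beta: float = 10.0
    dim: int = 2
    sigma_policy: str = "median_distance"
    init_policy: str = "pca"
    seed: int = 0
    max_iter: int = 500
    step_tol: float = 1e-6
    armijo_c: float = 1e-4
    armijo_shrink: float = 0.5
    armijo_alpha0: float = 1.0

    def __post_init__(self):
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be non-negative")
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        if not (0 < self.armijo_c < 1 and 0 < self.armijo_shrink < 1):
            raise ValueError("armijo_c and armijo_shrink must lie in (0, 1)")
        if self.armijo_alpha0 <= 0 or self.step_tol <= 0 or self.max_iter < 1:
            raise ValueError("armijo_alpha0, step_tol, max_iter must be positive")
        if self.init_policy not in ("pca", "random"):
            raise ValueError(f"unknown init_policy {self.init_policy!r}")
        # validate sigma policy eagerly so bad configs fail before any work
        self._resolve_fixed_sigma()

    def _resolve_fixed_sigma(self) -> Optional[float]:
        if self.sigma_policy == "median_distance":
            return None
        if self.sigma_policy.startswith("fixed:"):
            value = float(self.sigma_policy.split(":", 1)[1])
            if value <= 0:
                raise ValueError("fixed sigma must be strictly positive")
            return value
        raise ValueError(f"unknown sigma_policy {self.sigma_policy!r}")


@dataclass
class EmbeddingResult:
    """Fitted coordinates plus the optimization record."""

    coordinates: np.ndarray
    energy_trace: list
    n_iterations: int
    converged: bool
    config_used: EmbeddingConfig
    sigma: float = float("nan")
    inner_products: list = field(default_factory=list)  # <p_k, g_k> per iteration


@dataclass
class OptimizerState:
    """Reusable Cholesky factor of (L^P + mu I) for the spectral direction."""

    factorization: tuple
    mu: float
    iteration: int = 0
    warm_alpha: float = 1.0


class ArmijoStep(NamedTuple):
    alpha: float
    x_new: np.ndarray
    energy_new: float
    stalled: bool


# ---------------------------------------------------------------------------
# affinities and energy
# ---------------------------------------------------------------------------

def pairwise_sq_distances(points: np.ndarray) -> np.ndarray:
    """Dense matrix of squared Euclidean distances between rows.

    Exactly symmetric with an exactly zero diagonal. Raises on non-finite
    input, naming the first offending row.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    finite = np.isfinite(points).all(axis=1)
    if not finite.all():
        bad = int(np.flatnonzero(~finite)[0])
        raise ValueError(f"non-finite values in input row {bad}")
    if points.shape[0] == 1:
        return np.zeros((1, 1))
    d2 = squareform(pdist(points, metric="sqeuclidean"))
    np.maximum(d2, 0.0, out=d2)
    return d2


def resolve_sigma(expression: np.ndarray, config: EmbeddingConfig) -> float:
    """Gaussian bandwidth per the config policy.

    The default is the median of the off-diagonal pairwise Euclidean
    distances of the input rows — scale-adaptive and deterministic.
    """
    fixed = config._resolve_fixed_sigma()
    if fixed is not None:
        return fixed
    dists = pdist(np.asarray(expression, dtype=float), metric="euclidean")
    sigma = float(np.median(dists))
    if sigma <= 0:
        raise ValueError(
            "median pairwise distance is zero (all rows identical); "
            "use a fixed sigma or deduplicate the input"
        )
    return sigma


def build_affinities(
    dataset: TimeSeriesDataset,
    beta: float,
    sigma: float,
    side_distance: Optional[np.ndarray] = None,
) -> AffinityModel:
    """Construct the normalized attractive / repulsive / temporal weights.

    Unnormalized quantities: w^+_nm = exp(-||y_n - y_m||^2 / (2 sigma^2)),
    w^-_nm = ||y_n - y_m|| and side_nm = |t(n) - t(m)| (unless an explicit
    symmetric side-distance matrix replaces the time intervals). Diagonals
    are zeroed before normalization; N^+ = 1/sum(w^+) and the shared
    N^- = 1/sum(w^- + beta * side) make the off-diagonal sums of w^P and of
    (w^N + beta t) equal 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    y = dataset.expression
    n = y.shape[0]
    d2 = pairwise_sq_distances(y)

    w_plus_raw = np.exp(-d2 / (2.0 * sigma * sigma))
    np.fill_diagonal(w_plus_raw, 0.0)
    w_minus_raw = np.sqrt(d2)
    np.fill_diagonal(w_minus_raw, 0.0)

    if side_distance is None:
        t = dataset.stage_time
        side = np.abs(t[:, None] - t[None, :])
    else:
        side = np.asarray(side_distance, dtype=float)
        if side.shape != (n, n):
            raise ValueError(f"side_distance must be {n}x{n}, got {side.shape}")
        if not np.allclose(side, side.T):
            raise ValueError("side_distance must be symmetric")
        if side.min() < 0:
            raise ValueError("side_distance must be non-negative")
        side = 0.5 * (side + side.T)
    np.fill_diagonal(side, 0.0)

    plus_sum = w_plus_raw.sum()
    minus_sum = (w_minus_raw + beta * side).sum()
    if minus_sum <= 0:
        raise ValueError("degenerate dataset: repulsive normalizer undefined")
    if plus_sum <= 0:
        raise ValueError("degenerate dataset: attractive normalizer undefined")

    return AffinityModel(
        w_plus=w_plus_raw / plus_sum,
        w_minus=w_minus_raw / minus_sum,
        t_side=side / minus_sum,
        beta=float(beta),
        sigma=float(sigma),
    )


def _check_x(x: np.ndarray, model: AffinityModel) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != model.n_cells:
        raise ValueError(
            f"coordinates must be ({model.n_cells}, d), got {x.shape}"
        )
    return x


def tsee_energy(x: np.ndarray, model: AffinityModel, lam: float) -> float:
    """Evaluate the embedding energy at coordinates ``x`` (ordered-pair sums)."""
    x = _check_x(x, model)
    if lam < 0:
        raise ValueError("lam must be non-negative")
    d2 = pairwise_sq_distances(x)
    attractive = float((model.w_plus * d2).sum())
    repulsive = float((model.repulsive_weights() * np.exp(-d2)).sum())
    return attractive + lam * repulsive


def combined_laplacian(x: np.ndarray, model: AffinityModel, lam: float) -> np.ndarray:
    """Graph Laplacian L = D - W of the combined (signed) weight matrix.

    W_nm = w^P_nm - lam (w^N_nm + beta t_nm) exp(-||x_n - x_m||^2); rows of L
    sum to zero, so constant coordinate shifts lie in its null space.
    """
    x = _check_x(x, model)
    if lam < 0:
        raise ValueError("lam must be non-negative")
    d2 = pairwise_sq_distances(x)
    w = model.w_plus - lam * model.repulsive_weights() * np.exp(-d2)
    np.fill_diagonal(w, 0.0)
    return np.diag(w.sum(axis=1)) - w


def tsee_gradient(x: np.ndarray, model: AffinityModel, lam: float) -> np.ndarray:
    """Gradient of the energy: 4 L X with L from :func:`combined_laplacian`."""
    x = _check_x(x, model)
    return 4.0 * combined_laplacian(x, model, lam) @ x


# ---------------------------------------------------------------------------
# optimizer pieces
# ---------------------------------------------------------------------------

def attractive_laplacian_factor(model: AffinityModel) -> OptimizerState:
    """Cholesky-factorize (L^P + mu I) once for reuse across iterations.

    L^P is the Laplacian of the attractive weights (positive semi-definite);
    mu = 1e-10 x max diagonal entry of L^P is a positive, scale-aware jitter
    that makes the factor strictly positive definite. The Kronecker partial
    Hessian L^P (x) I_d + mu I then decouples into d identical solves.
    """
    wp = model.w_plus
    lp = np.diag(wp.sum(axis=1)) - wp
    mu = 1e-10 * float(lp.diagonal().max())
    if mu <= 0:
        mu = 1e-10
    try:
        factorization = cho_factor(lp + mu * np.eye(lp.shape[0]), lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise np.linalg.LinAlgError(
            "factorization of (L^P + mu I) failed; the attractive graph may be "
            "disconnected — retry with a larger jitter mu"
        ) from exc
    return OptimizerState(factorization=factorization, mu=mu)


def spectral_direction(state: OptimizerState, gradient: np.ndarray) -> np.ndarray:
    """Solve (L^P + mu I) p = -g column-by-column.

    Positive definiteness of the factorized matrix guarantees <p, g> < 0
    whenever g != 0, i.e. p is a descent direction.
    """
    g = np.asarray(gradient, dtype=float)
    if not np.isfinite(g).all():
        raise ValueError("non-finite gradient")
    return cho_solve(state.factorization, -g)


def _backtrack(energy_fn, x, p, slope, energy_old, c, shrink, alpha0,
               alpha_min=1e-14) -> ArmijoStep:
    """Armijo backtracking on an arbitrary energy callable.

    Shrinks alpha from alpha0 until energy(x + alpha p) <= E_old + c alpha
    <g, p>; below ``alpha_min`` without sufficient decrease the step stalls
    (alpha = 0, x unchanged) and the caller treats the iterate as converged.
    """
    if slope >= 0:
        raise ValueError("p is not a descent direction (<p, g> >= 0)")
    alpha = float(alpha0)
    while alpha >= alpha_min:
        x_new = x + alpha * p
        e_new = energy_fn(x_new)
        if e_new <= energy_old + c * alpha * slope:
            return ArmijoStep(alpha, x_new, e_new, stalled=False)
        alpha *= shrink
    return ArmijoStep(0.0, x, energy_old, stalled=True)


def armijo_step(
    x: np.ndarray,
    p: np.ndarray,
    g: np.ndarray,
    model: AffinityModel,
    lam: float,
    config: EmbeddingConfig,
    warm_alpha: float,
) -> ArmijoStep:
    """One Armijo-backtracked step of the embedding energy from ``x`` along ``p``."""
    slope = float((p * g).sum())
    energy_old = tsee_energy(x, model, lam)
    return _backtrack(
        lambda z: tsee_energy(z, model, lam),
        x, p, slope, energy_old,
        config.armijo_c, config.armijo_shrink, warm_alpha,
    )


# ---------------------------------------------------------------------------
# initialization and fitting
# ---------------------------------------------------------------------------

def _pca_scores(m: np.ndarray, k: int) -> np.ndarray:
    """First k principal-component scores with a deterministic sign convention.

    Each component is flipped so that the largest-magnitude entry of its
    loading vector is positive. Columns beyond the matrix rank are zero.
    """
    m = np.asarray(m, dtype=float)
    n_comp = min(k, m.shape[0] - 1 if m.shape[0] > 1 else 1, m.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(m)
    for j in range(n_comp):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    if n_comp < k:
        scores = np.hstack([scores, np.zeros((m.shape[0], k - n_comp))])
    return scores


def _initial_coordinates(dataset: TimeSeriesDataset, config: EmbeddingConfig) -> np.ndarray:
    if config.init_policy == "pca":
        scores = _pca_scores(dataset.expression, config.dim)
        sd = scores.std(axis=0)
        sd[sd < 1e-12] = 1.0  # leave degenerate (zero-variance) columns alone
        return scores / sd * 1e-2
    rng = np.random.default_rng(config.seed)
    return rng.normal(0.0, 1e-2, size=(dataset.n_cells, config.dim))


def fit_tsee(
    dataset: TimeSeriesDataset,
    config: Optional[EmbeddingConfig] = None,
    side_distance: Optional[np.ndarray] = None,
    x0: Optional[np.ndarray] = None,
) -> EmbeddingResult:
    """Fit the time-series elastic embedding.

    Resolves sigma, builds the affinities once (they depend only on the
    input, not on X), initializes coordinates per ``config.init_policy``
    (or from the explicit ``x0``), factorizes (L^P + mu I) once, and
    iterates spectral-direction / Armijo steps until the relative Frobenius
    displacement falls below ``step_tol`` or ``max_iter`` is reached.
    Deterministic given (dataset, config, side_distance, x0).
    """
    if config is None:
        config = EmbeddingConfig()
    n = dataset.n_cells
    if n < 2:
        raise ValueError("at least two cells are required")
    if n > _SIZE_WARN_THRESHOLD:
        logger.warning(
            "dense affinities for N=%d cells need O(N^2) memory; "
            "expect %d-element matrices", n, n * n,
        )

    sigma = resolve_sigma(dataset.expression, config)
    model = build_affinities(dataset, config.beta, sigma, side_distance)
    if x0 is not None:
        x = np.array(x0, dtype=float)
        if x.shape != (n, config.dim):
            raise ValueError(f"x0 must be ({n}, {config.dim}), got {x.shape}")
    else:
        x = _initial_coordinates(dataset, config)
    state = attractive_laplacian_factor(model)

    energy = tsee_energy(x, model, config.lam)
    trace = [energy]
    inner_products: list = []
    warm_alpha = config.armijo_alpha0
    converged = False
    iterations = 0

    for _ in range(config.max_iter):
        g = tsee_gradient(x, model, config.lam)
        p = spectral_direction(state, g)
        slope = float((p * g).sum())
        if slope >= 0:  # g == 0 exactly: already at a stationary point
            converged = True
            break
        inner_products.append(slope)
        step = _backtrack(
            lambda z: tsee_energy(z, model, config.lam),
            x, p, slope, energy,
            config.armijo_c, config.armijo_shrink, warm_alpha,
        )
        if step.stalled:
            converged = True
            break
        displacement = np.linalg.norm(step.x_new - x) / max(1.0, np.linalg.norm(x))
        x, energy = step.x_new, step.energy_new
        trace.append(energy)
        iterations += 1
        warm_alpha = min(step.alpha * 2.0, 1e2)
        if displacement < config.step_tol:
            converged = True
            break

    return EmbeddingResult(
        coordinates=x,
        energy_trace=trace,
        n_iterations=iterations,
        converged=converged,
        config_used=config,
        sigma=sigma,
        inner_products=inner_products,
    )
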