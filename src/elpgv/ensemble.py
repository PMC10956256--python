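"""Weight training for ensemble genomic prediction with a hybrid DE-PSO optimizer.

The ensemble prediction is an unnormalized weighted sum of the predictions of
``n`` base genomic-prediction methods,

    g_hat = sum_j W_j * p_j ,

and the weights ``W`` are trained to maximize the Pearson correlation between
``g_hat`` and a target vector (observed phenotypes, or "reference genetic
values" when phenotypes of the target cohort are unknown).  The optimizer is a
hybrid of differential evolution (mutation / crossover / greedy selection) and
particle swarm optimization (a velocity drift toward the incumbent best
weight), run for a fixed number of iterations and restarted many times; the
final weights are the average over restarts.

Because the fitness is a correlation, it is invariant to positive rescaling of
the weight vector, so no sum-to-one constraint is imposed; weights are instead
clamped to ``[w_min, w_max]`` whenever mutation would leave the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DEGENERATE_FITNESS",
    "BasePredictionSet",
    "SwarmConfig",
    "SwarmState",
    "EnsembleModel",
    "DegenerateFitnessError",
    "ensemble_predict",
    "fitness",
    "select_reference_method",
    "initialize_swarm",
    "de_mutation",
    "crossover",
    "greedy_select",
    "update_velocity",
    "train_weights_once",
    "train_elpgv",
]

#: Sentinel fitness for a degenerate (zero-variance) ensemble output.  It loses
#: every selection comparison against any finite correlation.
DEGENERATE_FITNESS = -np.inf


class DegenerateFitnessError(ValueError):
    """Raised when every candidate weight vector has degenerate fitness."""


@dataclass
class BasePredictionSet:
    """Aligned per-individual predictions from several named base methods.

    ``values[i, j]`` is the prediction of method ``method_names[j]`` for
    individual ``individual_ids[i]``.
    """

    individual_ids: np.ndarray
    method_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.method_names = list(self.method_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D individuals x methods matrix")
        n_ind, n_meth = self.values.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError(
                f"{len(self.individual_ids)} ids but {n_ind} prediction rows"
            )
        if len(self.method_names) != n_meth:
            raise ValueError(
                f"{len(self.method_names)} method names but {n_meth} columns"
            )
        if len(set(self.method_names)) != n_meth:
            raise ValueError("duplicate method names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("predictions contain missing or non-finite values")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_methods(self) -> int:
        return self.values.shape[1]

    def column(self, method: str) -> np.ndarray:
        return self.values[:, self.method_names.index(method)]

    def subset(self, mask_or_index) -> "BasePredictionSet":
        """Row-subset by boolean mask or integer index array."""
        return BasePredictionSet(
            self.individual_ids[mask_or_index],
            self.method_names,
            self.values[mask_or_index],
        )


@dataclass(frozen=True)
class SwarmConfig:
    """Hyperparameters of the DE-PSO weight optimizer.

    Defaults are the published operating point of the algorithm: weights
    searched in [0, 1], velocities in [-0.01, 0.01], 20 particles, DE scaling
    factor 0.5, crossover probability 0.3, inertia 1 with both acceleration
    factors 2, 25 iterations per restart and 100 restarts averaged.
    """

    w_min: float = 0.0
    w_max: float = 1.0
    v_min: float = -0.01
    v_max: float = 0.01
    m: int = 20
    f: float = 0.5
    cr: float = 0.3
    epsilon: float = 1.0
    c1: float = 2.0
    c2: float = 2.0
    max_iterations: int = 25
    repeats: int = 100
    seed: int = 0
    # Optional variants, off by default (see docs/methods.md).
    early_stop: bool = False
    early_stop_tol: float = 1e-8
    early_stop_window: int = 5
    per_dimension_crossover: bool = False

    def __post_init__(self) -> None:
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")
        if self.v_min > self.v_max:
            raise ValueError("v_min must not exceed v_max")
        if self.m < 4:
            raise ValueError("need at least 4 particles (DE mutation draws 3 peers)")
        if not 0.0 <= self.cr <= 1.0:
            raise ValueError("cr must lie in [0, 1]")
        if self.f <= 0:
            raise ValueError("scaling factor f must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class SwarmState:
    """Mutable state of one optimizer restart: particle weights, velocities,
    fitness values and the incumbent (best-ever) weight vector."""

    weights: np.ndarray       # m x n
    velocities: np.ndarray    # m x n
    fitness: np.ndarray       # length m
    incumbent: np.ndarray     # length n
    incumbent_fitness: float
    iteration: int = 0


@dataclass
class EnsembleModel:
    """Trained ensemble: averaged weights over restarts plus provenance."""

    method_names: list[str]
    averaged_weights: np.ndarray
    per_repeat_weights: np.ndarray       # repeats x n
    fitness_trajectories: np.ndarray     # repeats x (max_iterations + 1)
    mode: str                            # "phenotype" | "reference"
    reference_method: str | None = None

    def predict(self, predictions: BasePredictionSet) -> np.ndarray:
        return ensemble_predict(self.averaged_weights, predictions)


# ---------------------------------------------------------------------------
# core operations


def ensemble_predict(weights, predictions: BasePredictionSet) -> np.ndarray:
    """Weighted sum of base-method predictions, one value per individual."""
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != predictions.n_methods:
        raise ValueError(
            f"weight vector has length {w.size} but there are "
            f"{predictions.n_methods} methods"
        )
    return predictions.values @ w


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, or the degenerate sentinel when either vector is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0 or not np.isfinite(denom):
        return DEGENERATE_FITNESS
    return float((xc @ yc) / denom)


def fitness(weights, predictions: BasePredictionSet, target) -> float:
    """Correlation fitness of a weight vector against the target vector.

    Returns the Pearson correlation between the ensemble output and ``target``;
    a zero-variance ensemble output (e.g. all-zero weights) or constant target
    yields :data:`DEGENERATE_FITNESS`, which loses every selection comparison.
    """
    target = np.asarray(target, dtype=float).ravel()
    if target.size != predictions.n_individuals:
        raise ValueError("target length does not match number of individuals")
    return _pearson(ensemble_predict(weights, predictions), target)


class _FitnessContext:
    """Caches the centered target so each fitness call is one mat-vec."""

    def __init__(self, predictions: BasePredictionSet, target) -> None:
        self.values = predictions.values
        t = np.asarray(target, dtype=float).ravel()
        if t.size != predictions.n_individuals:
            raise ValueError("target length does not match number of individuals")
        self._tc = t - t.mean()
        self._tnorm = float(np.sqrt(self._tc @ self._tc))

    def __call__(self, w: np.ndarray) -> float:
        if self._tnorm == 0.0:
            return DEGENERATE_FITNESS
        pred = self.values @ w
        pc = pred - pred.mean()
        denom = self._tnorm * np.sqrt(pc @ pc)
        if denom == 0.0 or not np.isfinite(denom):
            return DEGENERATE_FITNESS
        return float((pc @ self._tc) / denom)

    def batch(self, W: np.ndarray) -> np.ndarray:
        """Fitness of each row of an m x n weight matrix."""
        if self._tnorm == 0.0:
            return np.full(W.shape[0], DEGENERATE_FITNESS)
        preds = self.values @ W.T                     # individuals x m
        pc = preds - preds.mean(axis=0)
        denom = self._tnorm * np.sqrt(np.einsum("ij,ij->j", pc, pc))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (self._tc @ pc) / denom
        out[(denom == 0.0) | ~np.isfinite(out)] = DEGENERATE_FITNESS
        return out


def select_reference_method(
    train_fits: BasePredictionSet, train_phenotypes
) -> str:
    """Pick the base method whose training-set fit best correlates with the
    observed training phenotypes ("best fitting effect").

    Its predictions on the target cohort then serve as reference genetic
    values when phenotypes there are unknown.  Ties break by method order.
    """
    y = np.asarray(train_phenotypes, dtype=float).ravel()
    rs = np.array(
        [_pearson(train_fits.values[:, j], y) for j in range(train_fits.n_methods)]
    )
    if np.all(rs == DEGENERATE_FITNESS):
        raise DegenerateFitnessError(
            "every base method has a degenerate correlation with the training "
            "phenotypes; cannot choose a reference method"
        )
    return train_fits.method_names[int(np.argmax(rs))]


def initialize_swarm(
    config: SwarmConfig,
    predictions: BasePredictionSet,
    target,
    rng: np.random.Generator,
) -> SwarmState:
    """Draw the initial particle weights and velocities uniformly inside their
    boxes and set the incumbent to the best-fitness particle."""
    n = predictions.n_methods
    if n < 2:
        raise ValueError("ensembling needs at least 2 base methods")
    fit_fn = _FitnessContext(predictions, target)
    weights = rng.uniform(config.w_min, config.w_max, size=(config.m, n))
    velocities = rng.uniform(config.v_min, config.v_max, size=(config.m, n))
    fit = fit_fn.batch(weights)
    if np.all(fit == DEGENERATE_FITNESS):
        raise DegenerateFitnessError(
            "all initial particles have degenerate fitness (constant ensemble "
            "output or constant target)"
        )
    best = int(np.argmax(fit))
    return SwarmState(
        weights=weights,
        velocities=velocities,
        fitness=fit,
        incumbent=weights[best].copy(),
        incumbent_fitness=float(fit[best]),
        iteration=0,
    )


def de_mutation(
    state: SwarmState,
    particle_index: int,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """DE/PSO mutation step for one particle.

    Returns the drift candidate ``P = W_i + V_i`` and the differential
    candidate ``H = W_k + F * (W_p - W_q)`` with ``k, p, q`` drawn without
    replacement from the other particles; both are clamped to the weight box.
    """
    m = state.weights.shape[0]
    i = particle_index
    peers = np.delete(np.arange(m), i)
    k, p, q = rng.choice(peers, size=3, replace=False)
    P = state.weights[i] + state.velocities[i]
    H = state.weights[k] + config.f * (state.weights[p] - state.weights[q])
    np.clip(P, config.w_min, config.w_max, out=P)
    np.clip(H, config.w_min, config.w_max, out=H)
    return P, H


def crossover(
    H_i: np.ndarray,
    W_prev_i: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Keep the mutated candidate with probability ``cr``, else the particle's
    previous weights.  One uniform draw per particle (whole-vector switch);
    ``per_dimension_crossover`` switches each component independently."""
    if config.per_dimension_crossover:
        u = rng.uniform(size=H_i.shape)
        return np.where(u <= config.cr, H_i, W_prev_i)
    return H_i.copy() if rng.uniform() <= config.cr else W_prev_i.copy()


def greedy_select(
    U_i: np.ndarray,
    P_i: np.ndarray,
    W_prev_i: np.ndarray,
    f_U: float,
    f_P: float,
    f_prev: float,
) -> tuple[np.ndarray, float]:
    """Two-stage greedy selection; ties favor the newer candidate.

    First the crossover candidate competes with the drift candidate, then the
    survivor competes with the particle's previous weights, so the particle's
    fitness never decreases.
    """
    if f_U >= f_P:
        G, f_G = U_i, f_U
    else:
        G, f_G = P_i, f_P
    if f_G >= f_prev:
        return G, f_G
    return W_prev_i, f_prev


def update_velocity(
    velocity_prev: np.ndarray,
    W_new_i: np.ndarray,
    W_prev_i: np.ndarray,
    incumbent_prev: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """PSO velocity update with inertia and two random accelerations, clamped
    to the velocity box."""
    r1, r2 = rng.uniform(size=2)
    v = (
        config.epsilon * velocity_prev
        + config.c1 * r1 * (W_new_i - W_prev_i)
        + config.c2 * r2 * (incumbent_prev - W_prev_i)
    )
    return np.clip(v, config.v_min, config.v_max)


def train_weights_once(
    predictions: BasePredictionSet,
    target,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """One optimizer restart: initialize, then iterate mutation / crossover /
    selection / velocity update for ``max_iterations`` iterations.

    Returns ``(incumbent weights, incumbent fitness, trajectory)`` where the
    trajectory holds the incumbent fitness after initialization and after each
    iteration; it is non-decreasing by construction of the greedy selection.
    """
    fit_fn = _FitnessContext(predictions, target)
    state = initialize_swarm(config, predictions, target, rng)
    trajectory = [state.incumbent_fitness]
    m = config.m
    all_idx = np.arange(m)

    for t in range(1, config.max_iterations + 1):
        # the whole generation mutates off the t-1 population
        prev_w = state.weights
        prev_fit = state.fitness
        incumbent_prev = state.incumbent

        kpq = np.empty((m, 3), dtype=int)
        for i in range(m):
            kpq[i] = rng.choice(np.delete(all_idx, i), size=3, replace=False)
        P = np.clip(prev_w + state.velocities, config.w_min, config.w_max)
        H = np.clip(
            prev_w[kpq[:, 0]] + config.f * (prev_w[kpq[:, 1]] - prev_w[kpq[:, 2]]),
            config.w_min,
            config.w_max,
        )
        if config.per_dimension_crossover:
            take = rng.uniform(size=prev_w.shape) <= config.cr
        else:
            take = (rng.uniform(size=m) <= config.cr)[:, None]
        U = np.where(take, H, prev_w)

        f_U = fit_fn.batch(U)
        f_P = fit_fn.batch(P)
        u_wins = (f_U >= f_P)[:, None]
        G = np.where(u_wins, U, P)
        f_G = np.where(u_wins[:, 0], f_U, f_P)
        g_wins = (f_G >= prev_fit)[:, None]
        new_w = np.where(g_wins, G, prev_w)
        new_fit = np.where(g_wins[:, 0], f_G, prev_fit)

        r12 = rng.uniform(size=(m, 2))
        vel = (
            config.epsilon * state.velocities
            + config.c1 * r12[:, :1] * (new_w - prev_w)
            + config.c2 * r12[:, 1:] * (incumbent_prev[None, :] - prev_w)
        )
        state.velocities = np.clip(vel, config.v_min, config.v_max)
        state.weights = new_w
        state.fitness = new_fit
        best = int(np.argmax(state.fitness))
        state.incumbent = state.weights[best].copy()
        state.incumbent_fitness = float(state.fitness[best])
        state.iteration = t
        trajectory.append(state.incumbent_fitness)
        if config.early_stop and len(trajectory) > config.early_stop_window:
            gain = trajectory[-1] - trajectory[-1 - config.early_stop_window]
            if gain < config.early_stop_tol:
                break

    return state.incumbent, state.incumbent_fitness, np.asarray(trajectory)


def train_elpgv(
    predictions: BasePredictionSet,
    config: SwarmConfig,
    phenotypes=None,
    reference_method: str | None = None,
) -> EnsembleModel:
    """Train ensemble weights and average them over ``config.repeats`` restarts.

    Exactly one of ``phenotypes`` (phenotype mode: train against observed
    values) or ``reference_method`` (reference mode: train against the named
    method's own predictions, the reference genetic values) must be given.
    Restart ``r`` uses seed ``config.seed + r`` so the averaged model is fully
    reproducible.
    """
    if (phenotypes is None) == (reference_method is None):
        raise ValueError("give exactly one of phenotypes or reference_method")
    if reference_method is not None:
        if reference_method not in predictions.method_names:
            raise ValueError(f"unknown reference method {reference_method!r}")
        target = predictions.column(reference_method)
        mode = "reference"
    else:
        target = np.asarray(phenotypes, dtype=float).ravel()
        mode = "phenotype"

    per_repeat = np.empty((config.repeats, predictions.n_methods))
    trajectories = []
    for r in range(config.repeats):
        rng = np.random.default_rng(config.seed + r)
        w, _, traj = train_weights_once(predictions, target, config, rng)
        per_repeat[r] = w
        trajectories.append(traj)
    max_len = max(len(t) for t in trajectories)
    traj_mat = np.full((config.repeats, max_len), np.nan)
    for r, t in enumerate(trajectories):
        traj_mat[r, : len(t)] = t
        traj_mat[r, len(t):] = t[-1]
    return EnsembleModel(
        method_names=list(predictions.method_names),
        averaged_weights=per_repeat.mean(axis=0),
        per_repeat_weights=per_repeat,
        fitness_trajectories=traj_mat,
        mode=mode,
        reference_method=reference_method,
    )
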