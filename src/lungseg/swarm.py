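"""Particle-swarm cluster-center search: PSO, IWPSO and GCPSO.

Each particle is a candidate vector of k cluster-center intensities in
[0, 1]. The swarm maximizes a cluster-validity fitness

    f(v) = sum_i  intercluster_i / intracluster ,

where, after assigning every pixel to its nearest center,
``intercluster_i`` is the mean distance from center i to the other
centers and ``intracluster`` is the global mean absolute deviation of
all pixels from their assigned center (floored at eps to keep the ratio
finite when every pixel sits exactly on a center). Empty clusters
contribute 0 to the sum. Large fitness means tight, well-separated
clusters. The intracluster term is global rather than per-cluster on
purpose: a per-cluster denominator goes to zero whenever two centers
straddle a point-mass intensity spike (clipped CT intensities have
them), so maximizing it degenerates into splitting spikes instead of
separating tissue modes.

Velocity updates:

* plain PSO keeps the previous velocity unweighted:
  ``v <- v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``;
* IWPSO multiplies it by an inertia weight w — constant (0.7) or redrawn
  each iteration as ``0.5 + U(0,1)/2`` — trading global exploration
  (large w) against local refinement (small w);
* GCPSO additionally replaces the update of the particle currently
  holding gbest by a guaranteed local search around gbest:
  ``x(t+1) = gbest + w*v + rho*(1 - 2r)``, r ~ U(0,1) per dimension,
  where the search radius rho doubles after more than ``sc`` consecutive
  gbest improvements and shrinks by ``rho_contract`` after more than
  ``fc`` consecutive failures. This guarantees the best particle never
  stalls with zero velocity at gbest, the classical premature-convergence
  failure of plain PSO.

All randomness flows from a single seeded generator, so runs are
bit-reproducible. For speed the fitness is evaluated on the image's
256-bin intensity histogram by default (equivalent to per-pixel
evaluation up to quantization for a 1-D feature); ``exact_fitness=True``
evaluates per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from ._validation import check_image
from .clustering import ClusterModel, _assign, objective_j

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "GCPSOState",
    "SwarmSegmenter",
    "fitness",
    "pso_step",
    "iwpso_step",
    "gcpso_step",
    "update_rho",
    "swarm_segment",
]

_EPS = 1e-9


@dataclass
class SwarmConfig:
    """Swarm hyperparameters.

    Defaults: 30 particles, 100 iterations, c1 = c2 = 2.0, velocity clamp
    0.2 (one fifth of the intensity range), constant inertia w = 0.7
    (random mode redraws w = 0.5 + U(0,1)/2 once per iteration), GCPSO
    thresholds sc = 15 successes / fc = 5 failures with radius expansion
    x2 and contraction x0.5.
    """

    n_particles: int = 30
    max_iter: int = 100
    c1: float = 2.0
    c2: float = 2.0
    w_mode: str = "constant"  # {none, constant, random}
    w: float = 0.7
    v_max: float = 0.2
    bounds: tuple[float, float] = (0.0, 1.0)
    sc: int = 15
    fc: int = 5
    rho0: float = 1.0
    rho_expand: float = 2.0
    rho_contract: float = 0.5
    patience: int | None = 25
    seed: int | None = None

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration coefficients must be nonnegative")
        if self.w_mode not in ("none", "constant", "random"):
            raise ValueError(f"unknown w_mode {self.w_mode!r}")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.sc <= 0 or self.fc <= 0:
            raise ValueError("sc and fc must be positive")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")


@dataclass
class SwarmState:
    """Positions, velocities and personal/global bests of the swarm."""

    x: np.ndarray  # (n_particles, k) candidate center vectors
    v: np.ndarray  # (n_particles, k)
    pbest_x: np.ndarray
    pbest_f: np.ndarray  # (n_particles,)
    gbest_x: np.ndarray  # (k,)
    gbest_f: float
    t: int = 0


@dataclass
class GCPSOState(SwarmState):
    """Swarm state extended with the guaranteed-convergence bookkeeping:
    search radius rho, consecutive success/failure counters, and tau, the
    index of the particle currently holding gbest."""

    rho: float = 1.0
    success_count: int = 0
    failure_count: int = 0
    tau: int = 0


def _make_fitness(img, *, exact: bool = False, n_bins: int = 256):
    """Build a fitness callable over center vectors for one image.

    Histogram mode pools the pixels into ``n_bins`` equal-width intensity
    bins and weights bin centers by their counts — for a 1-D feature this
    equals per-pixel evaluation up to the bin width.
    """
    x = check_image(img).ravel()
    if exact:
        values, counts = x, np.ones_like(x)
    else:
        counts, edges = np.histogram(x, bins=n_bins, range=(0.0, 1.0))
        keep = counts > 0
        values = ((edges[:-1] + edges[1:]) / 2.0)[keep]
        counts = counts[keep].astype(np.float64)

    n_total = counts.sum()

    def fitness_fn(centers: np.ndarray) -> float:
        centers = np.asarray(centers, dtype=np.float64)
        k = centers.size
        if k < 2:
            raise ValueError("fitness requires k >= 2 centers")
        d = np.abs(values[:, None] - centers[None, :])
        lbl = np.argmin(d, axis=1)
        intra = float(
            (counts * d[np.arange(values.size), lbl]).sum() / n_total
        )
        total = 0.0
        for i in range(k):
            if counts[lbl == i].sum() == 0:
                continue  # empty cluster contributes 0
            inter = float(np.mean(np.abs(np.delete(centers, i) - centers[i])))
            total += inter / max(intra, _EPS)
        return total

    return fitness_fn


def fitness(img, centers, *, exact: bool = True) -> float:
    """Cluster-validity fitness of ``centers`` on ``img`` (see module doc).

    Per-pixel (exact) evaluation by default; ``exact=False`` uses the
    256-bin histogram shortcut the optimizer itself uses.
    """
    return _make_fitness(img, exact=exact)(np.atleast_1d(centers))


def update_rho(
    rho: float, success_count: int, failure_count: int, config: SwarmConfig
) -> float:
    """Adapt the GCPSO search radius from the consecutive-event counters.

    Expands by ``rho_expand`` (default 2) once successes exceed sc,
    contracts by ``rho_contract`` (default 0.5) once failures exceed fc,
    and is left unchanged otherwise.
    """
    if success_count < 0 or failure_count < 0:
        raise ValueError("counters must be nonnegative")
    if success_count and failure_count:
        raise ValueError("at most one of success_count/failure_count may be nonzero")
    if success_count > config.sc:
        return config.rho_expand * rho
    if failure_count > config.fc:
        return config.rho_contract * rho
    return rho


def _clip_positions(x: np.ndarray, config: SwarmConfig) -> np.ndarray:
    lo, hi = config.bounds
    return np.clip(x, lo, hi)


def _update_bests(state: SwarmState, fitness_fn) -> None:
    """Re-evaluate all particles; pbest updates on strict improvement."""
    f = np.array([fitness_fn(p) for p in state.x])
    improved = f > state.pbest_f
    state.pbest_x[improved] = state.x[improved]
    state.pbest_f[improved] = f[improved]
    best = int(np.argmax(state.pbest_f))
    if state.pbest_f[best] > state.gbest_f:
        state.gbest_f = float(state.pbest_f[best])
        state.gbest_x = state.pbest_x[best].copy()


def _velocity_update(
    state: SwarmState, config: SwarmConfig, rng: np.random.Generator, w: float
) -> np.ndarray:
    r1 = rng.uniform(size=state.x.shape)
    r2 = rng.uniform(size=state.x.shape)
    v = (
        w * state.v
        + config.c1 * r1 * (state.pbest_x - state.x)
        + config.c2 * r2 * (state.gbest_x - state.x)
    )
    return np.clip(v, -config.v_max, config.v_max)


def _copy_state(state):
    kwargs = dict(
        x=state.x.copy(),
        v=state.v.copy(),
        pbest_x=state.pbest_x.copy(),
        pbest_f=state.pbest_f.copy(),
        gbest_x=state.gbest_x.copy(),
        gbest_f=state.gbest_f,
        t=state.t,
    )
    if isinstance(state, GCPSOState):
        kwargs.update(
            rho=state.rho,
            success_count=state.success_count,
            failure_count=state.failure_count,
            tau=state.tau,
        )
        return GCPSOState(**kwargs)
    return SwarmState(**kwargs)


def pso_step(
    state: SwarmState,
    config: SwarmConfig,
    fitness_fn,
    rng: np.random.Generator,
) -> SwarmState:
    """One plain-PSO iteration (no inertia weighting: w = 1)."""
    state = _copy_state(state)
    state.v = _velocity_update(state, config, rng, w=1.0)
    state.x = _clip_positions(state.x + state.v, config)
    _update_bests(state, fitness_fn)
    state.t += 1
    return state


def _draw_w(config: SwarmConfig, rng: np.random.Generator) -> float:
    if config.w_mode == "random":
        return 0.5 + rng.uniform() / 2.0
    return float(config.w)


def iwpso_step(
    state: SwarmState,
    config: SwarmConfig,
    fitness_fn,
    rng: np.random.Generator,
) -> SwarmState:
    """One inertia-weighted PSO iteration.

    In random mode the inertia weight is redrawn once per iteration and
    shared by all particles.
    """
    if config.w_mode not in ("constant", "random"):
        raise ValueError("iwpso requires w_mode 'constant' or 'random'")
    state = _copy_state(state)
    w = _draw_w(config, rng)
    state.v = _velocity_update(state, config, rng, w=w)
    state.x = _clip_positions(state.x + state.v, config)
    _update_bests(state, fitness_fn)
    state.t += 1
    return state


def gcpso_step(
    state: GCPSOState,
    config: SwarmConfig,
    fitness_fn,
    rng: np.random.Generator,
) -> GCPSOState:
    """One guaranteed-convergence PSO iteration.

    All particles but the gbest holder (tau) move by the inertia-weighted
    rule; tau is repositioned to ``gbest + w*v_tau + rho*(1 - 2r)``, a
    random probe of the rho-ball around gbest. Its implied velocity is
    exempt from the v_max clamp so the probe really lands where the rule
    says. After evaluation the success/failure counters and rho adapt,
    and tau is re-selected.
    """
    state = _copy_state(state)
    w = _draw_w(config, rng)
    v = _velocity_update(state, config, rng, w=w)
    tau = state.tau
    r = rng.uniform(size=state.x.shape[1])
    # canonical guaranteed-convergence update for the gbest holder:
    # v_tau = -x_tau + gbest + w*v_tau + rho*(1-2r), so that
    # x_tau(t+1) = gbest + w*v_tau + rho*(1-2r)
    v[tau] = (
        -state.x[tau]
        + state.gbest_x
        + w * state.v[tau]
        + state.rho * (1.0 - 2.0 * r)
    )
    state.v = v
    state.x = _clip_positions(state.x + state.v, config)
    prev_gbest = state.gbest_f
    _update_bests(state, fitness_fn)
    if state.gbest_f > prev_gbest:  # strict improvement counts as success
        state.success_count += 1
        state.failure_count = 0
    else:
        state.failure_count += 1
        state.success_count = 0
    state.rho = update_rho(state.rho, state.success_count, state.failure_count, config)
    state.tau = int(np.argmax(state.pbest_f))
    state.t += 1
    return state


def _init_state(
    img, k: int, config: SwarmConfig, rng: np.random.Generator, fitness_fn, variant: str
):
    lo, hi = config.bounds
    x = rng.uniform(lo, hi, size=(config.n_particles, k))
    v = np.zeros_like(x)
    f = np.array([fitness_fn(p) for p in x])
    best = int(np.argmax(f))
    common = dict(
        x=x,
        v=v,
        pbest_x=x.copy(),
        pbest_f=f,
        gbest_x=x[best].copy(),
        gbest_f=float(f[best]),
    )
    if variant == "gcpso":
        return GCPSOState(rho=config.rho0 * (hi - lo), tau=best, **common)
    return SwarmState(**common)


_STEPS = {"pso": pso_step, "iwpso": iwpso_step, "gcpso": gcpso_step}


class SwarmSegmenter(ClusterMixin, BaseEstimator):
    """Intensity segmentation by particle-swarm search over center vectors.

    Parameters
    ----------
    variant : {'pso', 'iwpso', 'gcpso'}, default='gcpso'
    k : int, default=3
        Number of cluster centers each particle encodes.
    n_particles, max_iter, c1, c2, w_mode, w, v_max, sc, fc, rho0,
    rho_expand, rho_contract, patience : see :class:`SwarmConfig`.
    exact_fitness : bool, default=False
        Evaluate the validity fitness per pixel instead of on the 256-bin
        intensity histogram.
    random_state : int or None
        Seed for all stochastic stages.

    Attributes
    ----------
    centers_ : (k,) ndarray, sorted ascending (gbest at termination)
    labels_ : (H, W) ndarray of nearest-center indices
    fitness_ : float, final gbest fitness
    fitness_trace_ : list of gbest fitness per iteration (nondecreasing)
    rho_trace_, success_trace_, failure_trace_ : GCPSO diagnostics
    """

    def __init__(
        self,
        variant: str = "gcpso",
        k: int = 3,
        n_particles: int = 30,
        max_iter: int = 100,
        c1: float = 2.0,
        c2: float = 2.0,
        w_mode: str = "constant",
        w: float = 0.7,
        v_max: float = 0.2,
        sc: int = 15,
        fc: int = 5,
        rho0: float = 1.0,
        rho_expand: float = 2.0,
        rho_contract: float = 0.5,
        patience: int | None = 25,
        exact_fitness: bool = False,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.k = k
        self.n_particles = n_particles
        self.max_iter = max_iter
        self.c1 = c1
        self.c2 = c2
        self.w_mode = w_mode
        self.w = w
        self.v_max = v_max
        self.sc = sc
        self.fc = fc
        self.rho0 = rho0
        self.rho_expand = rho_expand
        self.rho_contract = rho_contract
        self.patience = patience
        self.exact_fitness = exact_fitness
        self.random_state = random_state

    def _config(self) -> SwarmConfig:
        return SwarmConfig(
            n_particles=self.n_particles,
            max_iter=self.max_iter,
            c1=self.c1,
            c2=self.c2,
            w_mode=self.w_mode,
            w=self.w,
            v_max=self.v_max,
            sc=self.sc,
            fc=self.fc,
            rho0=self.rho0,
            rho_expand=self.rho_expand,
            rho_contract=self.rho_contract,
            patience=self.patience,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        if self.variant not in _STEPS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if int(self.k) < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        img = check_image(X)
        config = self._config()
        rng = np.random.default_rng(self.random_state)
        fitness_fn = _make_fitness(img, exact=self.exact_fitness)
        step = _STEPS[self.variant]
        state = _init_state(img, int(self.k), config, rng, fitness_fn, self.variant)
        trace = [state.gbest_f]
        rho_trace, succ_trace, fail_trace = [], [], []
        stall = 0
        for _ in range(config.max_iter):
            prev = state.gbest_f
            state = step(state, config, fitness_fn, rng)
            trace.append(state.gbest_f)
            if isinstance(state, GCPSOState):
                rho_trace.append(state.rho)
                succ_trace.append(state.success_count)
                fail_trace.append(state.failure_count)
            stall = 0 if state.gbest_f > prev else stall + 1
            if config.patience is not None and stall >= config.patience:
                break
        order = np.argsort(state.gbest_x, kind="stable")
        self.centers_ = state.gbest_x[order]
        self.labels_ = _assign(img.ravel(), self.centers_).reshape(img.shape)
        self.fitness_ = float(state.gbest_f)
        self.fitness_trace_ = list(map(float, trace))
        self.rho_trace_ = rho_trace
        self.success_trace_ = succ_trace
        self.failure_trace_ = fail_trace
        self.n_iter_ = state.t
        self.objective_ = objective_j(img, self.centers_)
        return self

    def predict(self, X):
        img = check_image(X)
        return _assign(img.ravel(), self.centers_).reshape(img.shape)

    def to_model(self) -> ClusterModel:
        """Package the fitted attributes as a :class:`ClusterModel`.

        The trace stored is the gbest-fitness trace (nondecreasing); the
        ``objective`` field carries the k-means objective of the final
        centers so swarm and Lloyd results are comparable.
        """
        return ClusterModel(
            centers=self.centers_,
            labels=self.labels_,
            objective=self.objective_,
            n_iter=self.n_iter_,
            converged=True,
            objective_trace=self.fitness_trace_,
        )


def swarm_segment(
    img, variant: str = "gcpso", k: int = 3, config: SwarmConfig | None = None
) -> ClusterModel:
    """Segment ``img`` with the chosen swarm variant; see :class:`SwarmSegmenter`."""
    config = config or SwarmConfig()
    est = SwarmSegmenter(
        variant=variant,
        k=k,
        n_particles=config.n_particles,
        max_iter=config.max_iter,
        c1=config.c1,
        c2=config.c2,
        w_mode=config.w_mode,
        w=config.w,
        v_max=config.v_max,
        sc=config.sc,
        fc=config.fc,
        rho0=config.rho0,
        rho_expand=config.rho_expand,
        rho_contract=config.rho_contract,
        patience=config.patience,
        random_state=config.seed,
    ).fit(img)
    return est.to_model()
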