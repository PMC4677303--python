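"""Finite-population pairwise-comparison dynamics in the small-mutation limit.

Strategies spread by imitation: at each time step two individuals of the
same population are sampled and the first copies the second with the Fermi
probability ``[1 + exp(-beta*(f_other - f_self))]^-1``, where ``beta`` is
the intensity of selection.  When mutations are rare (``mu << 1/N``) the
population is almost always homogeneous, and the dynamics reduce to a
Markov chain whose states are the homogeneous strategy profiles and whose
transitions are fixation probabilities of single mutants.

The AG couples two populations — N dictators and N receivers — that play
against each other but evolve within themselves ("players cannot change
role").  A mutant arises in one population at a time, so chain transitions
change exactly one coordinate of the (p, q) profile.  Because every game
interaction is with the opposite population, a mutant's payoff does not
depend on its own abundance, which makes the fixation probability available
in closed form; the general product formula is kept as a test oracle.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game_models import GameConfig, StrategyProfile, stage_payoffs

__all__ = [
    "PopulationSpec",
    "EmbeddedChain",
    "StationaryDistribution",
    "fermi_imitation_probability",
    "transition_probabilities",
    "fixation_probability",
    "build_embedded_chain",
    "stationary_distribution",
    "summarize",
    "beta_sweep",
    "DEFAULT_BETA_GRID",
]

#: Default logarithmic selection-intensity grid, spanning neutral drift
#: (1e-4) to effectively deterministic imitation (10).
DEFAULT_BETA_GRID: np.ndarray = np.logspace(-4, 1, 60)


@dataclass(frozen=True)
class PopulationSpec:
    """Population size and the strategy sets of the two populations."""

    N: int = 100
    dictator_strategies: tuple[int, ...] = tuple(range(1, 11))
    receiver_strategies: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "dictator_strategies", tuple(self.dictator_strategies)
        )
        object.__setattr__(
            self, "receiver_strategies", tuple(self.receiver_strategies)
        )
        if self.N < 2:
            raise ValueError(f"population size N must be >= 2, got {self.N}")
        for name in ("dictator_strategies", "receiver_strategies"):
            s = getattr(self, name)
            if name == "dictator_strategies" and not s:
                raise ValueError("dictator strategy set must be nonempty")
            if any(b <= a for a, b in zip(s, s[1:])):
                raise ValueError(f"{name} must be strictly increasing: {s}")

    @classmethod
    def from_config(cls, config: GameConfig, N: int = 100) -> "PopulationSpec":
        return cls(
            N=N,
            dictator_strategies=config.dictator_strategies,
            receiver_strategies=config.receiver_strategies,
        )

    @property
    def bipartite(self) -> bool:
        return len(self.receiver_strategies) > 0


@dataclass(frozen=True)
class EmbeddedChain:
    """Embedded Markov chain over homogeneous states in the rare-mutation limit."""

    states: tuple[StrategyProfile, ...]
    M: np.ndarray
    spec: PopulationSpec
    beta: float

    def __post_init__(self) -> None:
        n = len(self.states)
        if self.M.shape != (n, n):
            raise ValueError("transition matrix shape does not match state count")
        rows = self.M.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.M < -1e-15):
            raise ValueError("transition matrix has negative entries")


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary law of an embedded chain, with per-population marginals."""

    states: tuple[StrategyProfile, ...]
    probs: np.ndarray
    dictator_marginal: dict[int, float]
    receiver_marginal: dict[int, float]
    mean_p: float
    mean_q: float | None
    residual: float

    def as_frame(self) -> pd.DataFrame:
        """Joint distribution as a tidy table, ordered by (p, q)."""
        return pd.DataFrame(
            {
                "state_p": [s.p for s in self.states],
                "state_q": [s.q for s in self.states],
                "probability": self.probs,
            }
        )


def fermi_imitation_probability(f_self: float, f_other: float, beta: float) -> float:
    """Probability of copying the other player's strategy (Fermi rule).

    Equals 1/2 for equal payoffs or ``beta = 0`` (neutral drift) and tends
    to a step function as ``beta`` grows (deterministic imitation of the
    higher payoff).
    """
    if beta < 0:
        raise ValueError(f"selection intensity beta must be >= 0, got {beta}")
    x = beta * (f_other - f_self)
    # logistic, stable for |x| up to overflow range
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-min(x, 745.0)))
    e = math.exp(max(x, -745.0))
    return e / (1.0 + e)


def transition_probabilities(
    k: int, f_A: float, f_B: float, N: int, beta: float
) -> tuple[float, float]:
    """Birth/death probabilities for the number of A-mutants in one step.

    ``T_plus`` is the probability that a B-player imitates an A-player
    (raising the mutant count ``k`` by one), ``T_minus`` the reverse.  Both
    require sampling one player of each type, hence the ``k(N-k)/N^2``
    factor.  In this model payoffs come from the opposite population, so
    ``f_A`` and ``f_B`` do not depend on ``k``; arbitrary per-``k`` payoffs
    are nevertheless accepted.
    """
    if not (1 <= k <= N - 1):
        raise ValueError(f"mutant count k={k} outside [1, {N - 1}]")
    base = (k / N) * ((N - k) / N)
    return (
        base * fermi_imitation_probability(f_B, f_A, beta),
        base * fermi_imitation_probability(f_A, f_B, beta),
    )


def fixation_probability(f_A: float, f_B: float, N: int, beta: float) -> float:
    """Probability that a single A-mutant takes over a B-resident population.

    With constant payoffs the ratio ``T_minus/T_plus = exp(-beta*(f_A-f_B))
    = gamma`` is the same at every interior state, so the standard
    sum-of-products expression collapses to ``(1-gamma)/(1-gamma^N)``,
    with the neutral value 1/N at ``gamma = 1``.
    """
    if N < 2:
        raise ValueError(f"population size N must be >= 2, got {N}")
    if beta < 0:
        raise ValueError(f"selection intensity beta must be >= 0, got {beta}")
    x = beta * (f_A - f_B)
    if x == 0.0:
        return 1.0 / N
    if N * x < -700.0:
        # disfavoured mutant, deep in the exponential tail:
        # (e^-x - 1)/(e^-Nx - 1) ~ e^((N-1)x); underflows to 0 harmlessly
        return math.exp((N - 1) * x)
    return math.expm1(-x) / math.expm1(-N * x)


def _default_fitness_fns(config: GameConfig):
    def dictator_fitness(p: int, q: int | None) -> float:
        return stage_payoffs(p, q, config).dictator

    def receiver_fitness(q: int, p: int) -> float:
        return stage_payoffs(p, q, config).receiver

    return dictator_fitness, receiver_fitness


def build_embedded_chain(
    spec: PopulationSpec,
    config: GameConfig,
    beta: float,
    dictator_fitness: Callable[[int, int | None], float] | None = None,
    receiver_fitness: Callable[[int, int], float] | None = None,
    w_dictator: float | None = None,
) -> EmbeddedChain:
    """Assemble the rare-mutation transition matrix over homogeneous states.

    A transition changes the resident strategy of exactly one population.
    The probability of moving from ``(p, q)`` to ``(p', q)`` is
    ``w_D * rho_D(p' vs p | q) / (|S_D| - 1)``: the mutant appears among the
    dictators (weight ``w_D``), is any of the other dictator strategies with
    equal probability, and must fix.  Receiver transitions are symmetric
    with weight ``1 - w_D``.  The diagonal absorbs the remainder, so the
    stationary distribution is invariant to the weight split; ``w_dictator``
    defaults to 1/2 (1 for the single-population DG).

    ``dictator_fitness(p, q_resident)`` and ``receiver_fitness(q, p_resident)``
    give the payoff of a strategy against the opposite population's resident;
    defaults are the stage payoffs of ``config``.
    """
    if dictator_fitness is None or receiver_fitness is None:
        d_fit, r_fit = _default_fitness_fns(config)
        dictator_fitness = dictator_fitness or d_fit
        receiver_fitness = receiver_fitness or r_fit

    S_D = spec.dictator_strategies
    S_R = spec.receiver_strategies
    if not spec.bipartite:
        states = tuple(StrategyProfile(p, None) for p in S_D)
        w_D = 1.0
    else:
        states = tuple(StrategyProfile(p, q) for p in S_D for q in S_R)
        w_D = 0.5 if w_dictator is None else float(w_dictator)
        if not (0.0 <= w_D <= 1.0):
            raise ValueError(f"w_dictator must lie in [0, 1], got {w_D}")

    n = len(states)
    index = {(s.p, s.q): i for i, s in enumerate(states)}
    M = np.zeros((n, n))
    N = spec.N

    for i, s in enumerate(states):
        if len(S_D) > 1:
            f_res = dictator_fitness(s.p, s.q)
            for p_new in S_D:
                if p_new == s.p:
                    continue
                rho = fixation_probability(
                    dictator_fitness(p_new, s.q), f_res, N, beta
                )
                M[i, index[(p_new, s.q)]] = w_D * rho / (len(S_D) - 1)
        if spec.bipartite and len(S_R) > 1:
            f_res = receiver_fitness(s.q, s.p)
            for q_new in S_R:
                if q_new == s.q:
                    continue
                rho = fixation_probability(
                    receiver_fitness(q_new, s.p), f_res, N, beta
                )
                M[i, index[(s.p, q_new)]] = (1.0 - w_D) * rho / (len(S_R) - 1)
        off = M[i].sum()
        if off > 1.0 + 1e-12:
            raise RuntimeError(
                f"off-diagonal mass {off} > 1 at state {s}; inconsistent chain"
            )
        M[i, i] = 1.0 - off

    return EmbeddedChain(states=states, M=M, spec=spec, beta=beta)


def _marginal(states, probs, attr) -> dict[int, float]:
    out: dict[int, float] = {}
    for s, w in zip(states, probs):
        key = getattr(s, attr)
        if key is None:
            continue
        out[key] = out.get(key, 0.0) + float(w)
    return dict(sorted(out.items()))


def stationary_distribution(chain: EmbeddedChain) -> StationaryDistribution:
    """Stationary law: normalised eigenvector of M^T at eigenvalue 1.

    Fails loudly if the unit eigenvalue is not simple (a reducible chain
    would make the stationary law ambiguous); falls back to power iteration
    if the eigensolver's vector is numerically poor, and raises if the
    residual ``max|pi M - pi|`` still exceeds 1e-8.
    """
    M = chain.M
    eigvals, eigvecs = np.linalg.eig(M.T)
    near_one = np.where(np.abs(eigvals - 1.0) < 1e-9)[0]
    if len(near_one) == 0:
        raise RuntimeError("no eigenvalue within 1e-9 of 1; chain is not stochastic")
    if len(near_one) > 1:
        raise RuntimeError(
            f"{len(near_one)} eigenvalues within 1e-9 of 1; "
            "chain appears reducible, stationary distribution ambiguous"
        )
    v = np.real(eigvecs[:, near_one[0]])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    pi = v / v.sum()

    residual = float(np.max(np.abs(pi @ M - pi)))
    if residual > 1e-8:
        # power iteration fallback
        pi = np.full(len(chain.states), 1.0 / len(chain.states))
        for _ in range(200_000):
            nxt = pi @ M
            if np.max(np.abs(nxt - pi)) < 1e-14:
                pi = nxt
                break
            pi = nxt
        pi = np.clip(pi, 0.0, None)
        pi = pi / pi.sum()
        residual = float(np.max(np.abs(pi @ M - pi)))
        if residual > 1e-8:
            raise RuntimeError(
                f"stationary distribution did not converge (residual {residual:.2e})"
            )

    d_marg = _marginal(chain.states, pi, "p")
    r_marg = _marginal(chain.states, pi, "q")
    mean_p = float(sum(p * w for p, w in d_marg.items()))
    mean_q = float(sum(q * w for q, w in r_marg.items())) if r_marg else None
    return StationaryDistribution(
        states=chain.states,
        probs=pi,
        dictator_marginal=d_marg,
        receiver_marginal=r_marg,
        mean_p=mean_p,
        mean_q=mean_q,
        residual=residual,
    )


def summarize(dist: StationaryDistribution) -> dict:
    """Mean strategies and marginals of a stationary distribution."""
    return {
        "mean_p": dist.mean_p,
        "mean_q": dist.mean_q,
        "dictator_marginal": dict(dist.dictator_marginal),
        "receiver_marginal": dict(dist.receiver_marginal),
        "residual": dist.residual,
    }


def beta_sweep(
    spec: PopulationSpec,
    config: GameConfig,
    betas: Sequence[float] | None = None,
    **chain_kwargs,
) -> pd.DataFrame:
    """Mean resident strategies across a grid of selection intensities.

    Returns a table with columns ``beta, mean_p, mean_q``, one row per grid
    point, sorted by ``beta``.
    """
    if betas is None:
        betas = DEFAULT_BETA_GRID
    rows = []
    for beta in sorted(float(b) for b in betas):
        dist = stationary_distribution(
            build_embedded_chain(spec, config, beta, **chain_kwargs)
        )
        rows.append({"beta": beta, "mean_p": dist.mean_p, "mean_q": dist.mean_q})
    return pd.DataFrame(rows)
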