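"""Acceptance curves and the self-consistent anticipatory model.

The anticipatory fitness of a dictator donating ``p`` involves ``A(p)``,
the probability that a randomly drawn receiver from the evolving receiver
population accepts that donation.  But the receiver population itself
evolves against the dictators, whose dynamics depend on ``A``.  The coupled
system is closed as a fixed point: starting from the acceptance curve of a
uniform receiver population, we alternate (i) solving the embedded chain
under the current curve and (ii) recomputing the curve from the stationary
receiver marginal, with damping, until the curve stops changing.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evo_core import (
    PopulationSpec,
    StationaryDistribution,
    build_embedded_chain,
    stationary_distribution,
)
from .game_models import (
    GameConfig,
    accept_probability,
    anticipatory_dictator_fitness,
    stage_payoffs,
)

__all__ = [
    "AcceptanceCurve",
    "FixedPointResult",
    "acceptance_curve",
    "solve_self_consistent",
    "beta_delta_scan",
]


@dataclass(frozen=True)
class AcceptanceCurve:
    """A(p): probability a random receiver accepts a dictator donating p."""

    donations: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "donations", tuple(self.donations))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.donations) != len(self.values):
            raise ValueError("donations and values must have equal length")
        if any(v < -1e-12 or v > 1 + 1e-12 for v in self.values):
            raise ValueError("acceptance probabilities must lie in [0, 1]")

    def __call__(self, p: int) -> float:
        return self.as_dict()[p]

    def __getitem__(self, p: int) -> float:
        return self.as_dict()[p]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.donations, self.values))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p": self.donations, "A": self.values})

    def sup_distance(self, other: "AcceptanceCurve") -> float:
        if self.donations != other.donations:
            raise ValueError("curves defined on different donation grids")
        return float(
            np.max(np.abs(np.asarray(self.values) - np.asarray(other.values)))
        )


def acceptance_curve(
    receiver_marginal: Mapping[int, float], config: GameConfig
) -> AcceptanceCurve:
    """Average the threshold rule over a receiver strategy distribution.

    ``A(p) = sum_q P(q) * accept_probability(p, q)``.  The marginal must be
    normalised (to within 1e-8).
    """
    total = sum(receiver_marginal.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"receiver marginal sums to {total}, expected 1")
    donations = config.dictator_strategies
    # renormalise so that a curve averaged over all-accepting thresholds is
    # exactly 1, not 1 - eps, even when the marginal carries rounding dust
    values = [
        sum(
            w * accept_probability(p, q, config)
            for q, w in receiver_marginal.items()
        )
        / total
        for p in donations
    ]
    return AcceptanceCurve(donations=donations, values=values)


def _uniform_receiver_marginal(spec: PopulationSpec) -> dict[int, float]:
    qs = spec.receiver_strategies
    return {q: 1.0 / len(qs) for q in qs}


@dataclass(frozen=True)
class FixedPointResult:
    """Converged (stationary distribution, acceptance curve) pair."""

    distribution: StationaryDistribution
    curve: AcceptanceCurve
    iterations: int
    residual: float
    converged: bool
    beta: float
    delta: float


class FixedPointError(RuntimeError):
    """Self-consistent solve failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def _solve_chain_for_curve(
    spec: PopulationSpec, config: GameConfig, beta: float, curve: AcceptanceCurve
) -> StationaryDistribution:
    curve_map = curve.as_dict()

    def dictator_fitness(p: int, q: int | None) -> float:
        return anticipatory_dictator_fitness(p, q, curve_map, config)

    def receiver_fitness(q: int, p: int) -> float:
        return stage_payoffs(p, q, config).receiver

    chain = build_embedded_chain(
        spec,
        config,
        beta,
        dictator_fitness=dictator_fitness,
        receiver_fitness=receiver_fitness,
    )
    return stationary_distribution(chain)


def solve_self_consistent(
    spec: PopulationSpec,
    config: GameConfig,
    beta: float,
    tol: float = 1e-8,
    max_iter: int = 200,
    damping: float = 0.5,
    initial_curve: AcceptanceCurve | None = None,
    self_consistent: bool = True,
) -> FixedPointResult:
    """Solve the coupled (dictator fitness, receiver population) fixed point.

    Parameters
    ----------
    damping : float
        Fraction of the newly computed curve mixed into the iterate; plain
        iteration (damping=1) can oscillate between two curves, 0.5 is a
        robust default.
    initial_curve : AcceptanceCurve, optional
        Starting curve; defaults to the curve of a uniform receiver
        population.
    self_consistent : bool
        If False, perform a single chain solve with the initial (uniform)
        curve — a one-shot baseline for comparison, not iterated.

    Raises
    ------
    FixedPointError
        If the sup-norm change of the curve has not dropped below ``tol``
        within ``max_iter`` iterations.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if not (0 < damping <= 1):
        raise ValueError(f"damping must lie in (0, 1], got {damping}")
    if not spec.bipartite:
        raise ValueError("self-consistent solve requires a receiver population")

    curve = initial_curve or acceptance_curve(
        _uniform_receiver_marginal(spec), config
    )

    if not self_consistent:
        dist = _solve_chain_for_curve(spec, config, beta, curve)
        return FixedPointResult(
            distribution=dist,
            curve=curve,
            iterations=1,
            residual=float("nan"),
            converged=True,
            beta=beta,
            delta=config.delta,
        )

    vals_old = np.asarray(curve.values)
    residual = float("inf")
    for it in range(1, max_iter + 1):
        dist = _solve_chain_for_curve(spec, config, beta, curve)
        new_curve = acceptance_curve(dist.receiver_marginal, config)
        vals_new = np.asarray(new_curve.values)
        residual = float(np.max(np.abs(vals_new - vals_old)))
        vals_old = damping * vals_new + (1.0 - damping) * vals_old
        curve = AcceptanceCurve(donations=curve.donations, values=tuple(vals_old))
        if residual < tol:
            return FixedPointResult(
                distribution=dist,
                curve=new_curve,
                iterations=it,
                residual=residual,
                converged=True,
                beta=beta,
                delta=config.delta,
            )
    raise FixedPointError(
        f"fixed point not reached in {max_iter} iterations "
        f"(last residual {residual:.3e})",
        residual,
    )


def beta_delta_scan(
    spec: PopulationSpec,
    config: GameConfig,
    beta_grid: Sequence[float],
    delta_grid: Sequence[float],
    target_mean_p: float | None = None,
    **solver_kwargs,
) -> pd.DataFrame:
    """Grid of self-consistent solves over selection intensity and delta.

    Returns a table sorted by (delta, beta) with columns ``beta, delta,
    mean_p, mean_q, converged, iterations, residual`` and, when a target
    mean donation is given, ``best_fit`` marking the cell of each delta row
    whose mean donation is closest to the target.  Non-convergent cells are
    recorded (converged=False) without aborting the scan.
    """
    if len(beta_grid) == 0 or len(delta_grid) == 0:
        raise ValueError("beta_grid and delta_grid must be nonempty")
    rows = []
    for delta in sorted(float(d) for d in delta_grid):
        cfg = config.replace(delta=delta)
        for beta in sorted(float(b) for b in beta_grid):
            try:
                res = solve_self_consistent(spec, cfg, beta, **solver_kwargs)
                rows.append(
                    {
                        "beta": beta,
                        "delta": delta,
                        "mean_p": res.distribution.mean_p,
                        "mean_q": res.distribution.mean_q,
                        "converged": True,
                        "iterations": res.iterations,
                        "residual": res.residual,
                    }
                )
            except FixedPointError as exc:
                rows.append(
                    {
                        "beta": beta,
                        "delta": delta,
                        "mean_p": float("nan"),
                        "mean_q": float("nan"),
                        "converged": False,
                        "iterations": solver_kwargs.get("max_iter", 200),
                        "residual": exc.residual,
                    }
                )
    table = pd.DataFrame(rows).sort_values(["delta", "beta"], ignore_index=True)
    if target_mean_p is not None:
        table["best_fit"] = False
        for delta, group in table.groupby("delta"):
            ok = group[group["converged"]]
            if len(ok):
                idx = (ok["mean_p"] - target_mean_p).abs().idxmin()
                table.loc[idx, "best_fit"] = True
    return table
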