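"""Stage games: Dictator Game (DG) and Anticipation Game (AG).

The DG is a one-sided split of an endowment of ``X`` Experimental Currency
Units (ECUs): the dictator donates an integer ``p`` (at least 1, so the
subgame perfect equilibrium is unique) and keeps ``X - p``.  The AG prepends
a matching phase: each round a receiver, paired at random with a dictator,
decides whether to play with them based on the dictator's reputation.  A
receiver strategy is an integer threshold ``q`` — the minimum donation she
expects; rejection leaves both players with zero.  The noisy AG informs the
receiver about her partner's past action only with probability ``omega``;
when uninformed she falls back on a baseline expectation ``q0``.

The module also defines the anticipatory dictator fitness, which mixes the
current stage payoff with the payoff expected in the next round, weighted by
the probability ``A(p)`` that a randomly drawn future receiver accepts a
dictator donating ``p``.  The weight ``delta`` in [0, 1] measures how much
the dictator's success depends on that future acceptance.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass, fields
from enum import Enum
from typing import Union

__all__ = [
    "Variant",
    "AcceptanceMode",
    "GameConfig",
    "StrategyProfile",
    "StagePayoffs",
    "effective_expectation",
    "accept_probability",
    "stage_payoffs",
    "anticipatory_dictator_fitness",
]


class Variant(str, Enum):
    """Game variant: plain DG, AG (informed receivers) or noisy AG."""

    DG = "dg"
    AG = "ag"
    NOISY_AG = "noisy_ag"


class AcceptanceMode(str, Enum):
    """Semantics of partial information (``omega`` < 1).

    THRESHOLD_MIX: the receiver's effective expectation is the convex
    combination ``omega*q + (1-omega)*q0`` and she accepts iff the donation
    meets it.  BERNOULLI_MIX: each round is an information coin-flip — with
    probability ``omega`` she applies her own threshold ``q``, otherwise the
    baseline ``q0``.  The two coincide at ``omega`` in {0, 1}.
    """

    THRESHOLD_MIX = "threshold_mix"
    BERNOULLI_MIX = "bernoulli_mix"


_VARIANT_OMEGA = {Variant.DG: 0.0, Variant.AG: 1.0, Variant.NOISY_AG: 0.5}


@dataclass(frozen=True)
class GameConfig:
    """Full configuration of a stage game.

    Parameters
    ----------
    variant : Variant
        DG, AG or NOISY_AG.  In the DG the receiver has no decision and
        ``omega``/``q_max`` are irrelevant.
    endowment : int
        X, the per-round endowment in ECUs (default 10).
    p_min, p_max : int
        Range of dictator donations; 1..X by default.
    q_max : int
        Cap on receiver expectations.  The basic model uses ``q_max = p_max``;
        the restricted model caps it at 5 (half the endowment), matching the
        observation that donations of 5 or more are always accepted.
    omega : float
        Probability the receiver knows the dictator's past action.  Defaults
        per variant: 1 for AG, 0.5 for NOISY_AG, irrelevant (0) for DG.
    q0 : float
        Baseline expectation of an uninformed receiver, in ECUs.
    delta : float
        Future-importance weight of the anticipatory fitness; 0 recovers the
        basic model.
    acceptance_mode : AcceptanceMode
        Semantics of partial information, see :class:`AcceptanceMode`.
    """

    variant: Variant = Variant.AG
    endowment: int = 10
    p_min: int = 1
    p_max: int | None = None
    q_max: int | None = None
    omega: float | None = None
    q0: float = 2.0
    delta: float = 0.0
    acceptance_mode: AcceptanceMode = AcceptanceMode.THRESHOLD_MIX

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant(self.variant))
        object.__setattr__(
            self, "acceptance_mode", AcceptanceMode(self.acceptance_mode)
        )
        if self.p_max is None:
            object.__setattr__(self, "p_max", self.endowment)
        if self.q_max is None:
            object.__setattr__(self, "q_max", self.p_max)
        if self.omega is None:
            object.__setattr__(self, "omega", _VARIANT_OMEGA[self.variant])
        if not (1 <= self.p_min <= self.p_max <= self.endowment):
            raise ValueError(
                f"require 1 <= p_min <= p_max <= endowment, got "
                f"p_min={self.p_min}, p_max={self.p_max}, X={self.endowment}"
            )
        if not (1 <= self.q_max <= self.p_max):
            raise ValueError(f"require 1 <= q_max <= p_max, got q_max={self.q_max}")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        if self.q0 < 0:
            raise ValueError(f"q0 must be nonnegative, got {self.q0}")

    @property
    def dictator_strategies(self) -> tuple[int, ...]:
        return tuple(range(self.p_min, self.p_max + 1))

    @property
    def receiver_strategies(self) -> tuple[int, ...]:
        """Receiver thresholds; empty for the DG (she can only play)."""
        if self.variant is Variant.DG:
            return ()
        return tuple(range(1, self.q_max + 1))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["variant"] = self.variant.value
        d["acceptance_mode"] = self.acceptance_mode.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GameConfig":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown GameConfig fields: {sorted(extra)}")
        return cls(**dict(d))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GameConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "GameConfig":
        # dataclasses.replace would re-trigger defaults for None fields;
        # pass the resolved values through explicitly.
        base = self.to_dict()
        base.update(changes)
        return GameConfig.from_dict(base)


@dataclass(frozen=True)
class StrategyProfile:
    """A homogeneous (dictator, receiver) strategy pair.

    ``q`` is None in the DG, where the receiver has no decision.
    """

    p: int
    q: int | None = None


@dataclass(frozen=True)
class StagePayoffs:
    dictator: float
    receiver: float
    accepted: bool


def _check_strategies(p: int, q: int | None, config: GameConfig) -> None:
    if not (config.p_min <= p <= config.p_max):
        raise ValueError(f"donation p={p} outside [{config.p_min}, {config.p_max}]")
    if config.variant is not Variant.DG:
        if q is None or not (1 <= q <= config.q_max):
            raise ValueError(f"threshold q={q} outside [1, {config.q_max}]")


def effective_expectation(q: float, omega: float, q0: float) -> float:
    """Effective receiver expectation under partial information.

    With probability ``omega`` the receiver knows the dictator's past action
    and applies her own threshold ``q``; otherwise she expects the baseline
    ``q0``.  The effective expectation is the convex combination
    ``omega*q + (1 - omega)*q0``.
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    return omega * q + (1.0 - omega) * q0


def accept_probability(p: int, q: int | None, config: GameConfig) -> float:
    """Probability that a receiver with threshold ``q`` accepts donation ``p``.

    The DG has no rejection, so it always returns 1.  Ties accept: a
    donation exactly meeting the expectation is enough ("at least q").
    """
    _check_strategies(p, q, config)
    if config.variant is Variant.DG:
        return 1.0
    if config.acceptance_mode is AcceptanceMode.THRESHOLD_MIX:
        return 1.0 if p >= effective_expectation(q, config.omega, config.q0) else 0.0
    informed = 1.0 if p >= q else 0.0
    uninformed = 1.0 if p >= config.q0 else 0.0
    return config.omega * informed + (1.0 - config.omega) * uninformed


def stage_payoffs(p: int, q: int | None, config: GameConfig) -> StagePayoffs:
    """Expected single-round payoffs of a (p, q) encounter.

    On acceptance the dictator keeps ``X - p`` and the receiver gets ``p``;
    on rejection both get zero.  With probabilistic acceptance the payoffs
    are expectations over the information noise.
    """
    a = accept_probability(p, q, config)
    return StagePayoffs(
        dictator=(config.endowment - p) * a,
        receiver=p * a,
        accepted=a > 0.0,
    )


CurveLike = Union[Mapping[int, float], Callable[[int], float]]


def _curve_value(curve: CurveLike, p: int) -> float:
    try:
        if callable(curve):
            return float(curve(p))
        return float(curve[p])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"acceptance curve does not cover donation p={p}") from exc


def anticipatory_dictator_fitness(
    p: int, q: int | None, curve: CurveLike, config: GameConfig
) -> float:
    """Dictator fitness mixing current and anticipated future payoff.

    When the current interaction occurs, the dictator earns the weighted
    combination ``(1 - delta)*(X - p) + delta*(X - p)*A(p)``: the current
    payoff, plus the payoff of the next round discounted by the probability
    ``A(p)`` that a newly matched receiver accepts the donation ``p`` now on
    record.  When the current receiver rejects, present and future are both
    lost and the fitness is zero.  Under information noise the current
    acceptance is an expectation, so the whole expression is scaled by the
    current acceptance probability.

    ``delta = 0`` recovers the basic stage payoff exactly; ``delta = 1``
    makes success depend solely on future acceptance.
    """
    a_now = accept_probability(p, q, config)
    future = _curve_value(curve, p)
    return a_now * ((1.0 - config.delta) + config.delta * future) * (
        config.endowment - p
    )
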