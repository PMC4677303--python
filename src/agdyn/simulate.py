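"""Forward simulation: explicit-mutation Monte Carlo and synthetic sessions.

Two independent checks on the analytic machinery live here.  The Monte
Carlo simulator runs the full pairwise-comparison process with an explicit
per-update mutation probability ``mu``; at ``mu << 1/N`` its time-averaged
strategy frequencies converge to the embedded-chain stationary law.  The
session generator emulates the behavioural protocol itself — 30 rounds of
random matching, a three-round reputation history, information coin-flips —
producing tables the summary-statistics code can be exercised on.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .evo_core import PopulationSpec, StationaryDistribution
from .game_models import GameConfig, Variant, stage_payoffs

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "monte_carlo",
    "generate_sessions",
    "session_summaries",
    "stationary_strategy_source",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo run parameters; the seed is mandatory."""

    spec: PopulationSpec
    game: GameConfig
    beta: float
    mu: float
    steps: int
    seed: int
    burn_in: int = 0
    sample_every: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mutation probability mu must lie in [0,1], got {self.mu}")
        if self.steps <= self.burn_in:
            raise ValueError("steps must exceed burn_in")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class SimulationResult:
    """Time-averaged post-burn-in strategy frequencies and a trajectory."""

    dictator_frequencies: dict[int, float]
    receiver_frequencies: dict[int, float]
    trajectory_mean_p: np.ndarray
    n_samples: int


@njit(cache=True)
def _mc_kernel(
    sD, sR, cD, cR, piD, piR, pvals, beta, mu, steps, burn_in, sample_every, seed,
    two_pops,
):
    np.random.seed(seed)
    N = sD.shape[0]
    nD = cD.shape[0]
    nR = cR.shape[0]
    accD = np.zeros(nD)
    accR = np.zeros(nR)
    n_traj = (steps - burn_in - 1) // sample_every + 1
    traj = np.zeros(n_traj)
    occ_steps = 0

    # While both populations are homogeneous an imitation update is a no-op,
    # so the waiting time to the next mutation is geometric in mu and can be
    # skipped in a single draw, crediting the skipped occupancy exactly.
    # This leaves the process law unchanged and makes the rare-mutation
    # regime (mu << 1/N) affordable.
    homD = False
    homR = two_pops == 0
    for k in range(nD):
        if cD[k] == N:
            homD = True
    if two_pops == 1:
        for k in range(nR):
            if cR[k] == N:
                homR = True

    t = 0
    while t < steps:
        if homD and homR and mu > 0.0:
            # next mutation lands at the end of step t + skip - 1
            skip = np.random.geometric(mu)
            mutate = t + skip <= steps
            n_occ = skip if mutate else steps - t
            lo = t if t > burn_in else burn_in
            hi = t + n_occ - 1
            if hi >= lo:
                w = hi - lo + 1
                occ_steps += w
                mean_p = 0.0
                for k in range(nD):
                    accD[k] += cD[k] * w
                    mean_p += cD[k] * pvals[k]
                for k in range(nR):
                    accR[k] += cR[k] * w
                m0 = (lo - burn_in + sample_every - 1) // sample_every
                m1 = (hi - burn_in) // sample_every
                for m in range(m0, m1 + 1):
                    traj[m] = mean_p / N
            t += n_occ
            if mutate:
                if two_pops == 1 and np.random.random() < 0.5:
                    i = np.random.randint(N)
                    new = np.random.randint(nR)
                    cR[sR[i]] -= 1
                    cR[new] += 1
                    sR[i] = new
                    homR = cR[new] == N
                else:
                    i = np.random.randint(N)
                    new = np.random.randint(nD)
                    cD[sD[i]] -= 1
                    cD[new] += 1
                    sD[i] = new
                    homD = cD[new] == N
            continue

        # composition at the start of this step
        if t >= burn_in:
            occ_steps += 1
            mean_p = 0.0
            for k in range(nD):
                accD[k] += cD[k]
                mean_p += cD[k] * pvals[k]
            for k in range(nR):
                accR[k] += cR[k]
            if (t - burn_in) % sample_every == 0:
                traj[(t - burn_in) // sample_every] = mean_p / N

        if two_pops == 1 and np.random.random() < 0.5:
            # receiver population update
            i = np.random.randint(N)
            if np.random.random() < mu:
                new = np.random.randint(nR)
                cR[sR[i]] -= 1
                cR[new] += 1
                sR[i] = new
                homR = cR[new] == N
            else:
                j = np.random.randint(N - 1)
                if j >= i:
                    j += 1
                a = sR[i]
                b = sR[j]
                if a != b:
                    fa = 0.0
                    fb = 0.0
                    for k in range(nD):
                        fa += piR[a, k] * cD[k]
                        fb += piR[b, k] * cD[k]
                    x = beta * (fb - fa) / N
                    if x >= 0.0:
                        prob = 1.0 / (1.0 + np.exp(-x))
                    else:
                        e = np.exp(x)
                        prob = e / (1.0 + e)
                    if np.random.random() < prob:
                        cR[a] -= 1
                        cR[b] += 1
                        sR[i] = b
                        homR = cR[b] == N
        else:
            # dictator population update
            i = np.random.randint(N)
            if np.random.random() < mu:
                new = np.random.randint(nD)
                cD[sD[i]] -= 1
                cD[new] += 1
                sD[i] = new
                homD = cD[new] == N
            else:
                j = np.random.randint(N - 1)
                if j >= i:
                    j += 1
                a = sD[i]
                b = sD[j]
                if a != b:
                    fa = 0.0
                    fb = 0.0
                    for k in range(nR):
                        fa += piD[a, k] * cR[k]
                        fb += piD[b, k] * cR[k]
                    x = beta * (fb - fa) / N
                    if x >= 0.0:
                        prob = 1.0 / (1.0 + np.exp(-x))
                    else:
                        e = np.exp(x)
                        prob = e / (1.0 + e)
                    if np.random.random() < prob:
                        cD[a] -= 1
                        cD[b] += 1
                        sD[i] = b
                        homD = cD[b] == N
        t += 1
    return accD, accR, traj, occ_steps


def monte_carlo(config: SimulationConfig) -> SimulationResult:
    """Simulate the pairwise-comparison process with explicit mutation.

    Each update draws a population (1/2 each in the bipartite AG), then a
    learner.  With probability ``mu`` the learner adopts a uniformly random
    strategy of its population (possibly its own — mutation is
    strategy-uniform so ``mu`` is comparable across strategy-set sizes);
    otherwise it meets a distinct random role model of the same population
    and imitates with the Fermi probability, where each strategy's payoff
    is its average stage payoff against the current composition of the
    opposite population.  Bit-reproducible under a fixed seed.
    """
    spec, game = config.spec, config.game
    S_D = spec.dictator_strategies
    S_R = spec.receiver_strategies
    two_pops = 1 if spec.bipartite else 0
    N = spec.N

    # payoff matrices indexed by strategy position
    if spec.bipartite:
        piD = np.array(
            [[stage_payoffs(p, q, game).dictator for q in S_R] for p in S_D]
        )
        piR = np.array(
            [[stage_payoffs(p, q, game).receiver for p in S_D] for q in S_R]
        )
    else:
        piD = np.array([[stage_payoffs(p, None, game).dictator] for p in S_D])
        piR = np.zeros((1, len(S_D)))

    rng = np.random.default_rng(config.seed)
    sD = rng.integers(0, len(S_D), size=N).astype(np.int64)
    nR = len(S_R) if spec.bipartite else 1
    sR = rng.integers(0, nR, size=N).astype(np.int64)
    cD = np.bincount(sD, minlength=len(S_D)).astype(np.int64)
    cR = np.bincount(sR, minlength=nR).astype(np.int64)

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    accD, accR, traj, occ_steps = _mc_kernel(
        sD,
        sR,
        cD,
        cR,
        piD,
        piR,
        np.asarray(S_D, dtype=np.float64),
        float(config.beta),
        float(config.mu),
        int(config.steps),
        int(config.burn_in),
        int(config.sample_every),
        kernel_seed,
        two_pops,
    )
    if occ_steps == 0:
        raise RuntimeError("no post-burn-in occupancy; increase steps")
    freqD = {p: accD[i] / (occ_steps * N) for i, p in enumerate(S_D)}
    if spec.bipartite:
        freqR = {q: accR[i] / (occ_steps * N) for i, q in enumerate(S_R)}
    else:
        freqR = {}
    return SimulationResult(
        dictator_frequencies=freqD,
        receiver_frequencies=freqR,
        trajectory_mean_p=traj,
        n_samples=len(traj),
    )


# ---------------------------------------------------------------------------
# synthetic behavioural sessions
# ---------------------------------------------------------------------------

SESSION_COLUMNS = [
    "session",
    "round",
    "pair",
    "dictator",
    "receiver",
    "informed",
    "donation",
    "accepted",
    "dictator_payoff",
    "receiver_payoff",
    "history",
]

#: rounds of forced standard-DG play that seed the reputation history
N_INITIATION_ROUNDS = 3
N_ROUNDS = 30
HISTORY_LENGTH = 3


def stationary_strategy_source(
    dist: StationaryDistribution,
) -> Callable[[np.random.Generator, int], tuple[np.ndarray, np.ndarray]]:
    """Draw (p, q) strategy pairs from a stationary joint distribution."""

    ps = np.array([s.p for s in dist.states])
    qs = np.array([s.q if s.q is not None else 0 for s in dist.states])
    probs = np.asarray(dist.probs)

    def draw(rng: np.random.Generator, n: int):
        idx = rng.choice(len(ps), size=n, p=probs / probs.sum())
        return ps[idx], qs[idx]

    return draw


def _as_source(strategy_source):
    if callable(strategy_source):
        return strategy_source
    pairs = list(strategy_source)

    def draw(rng: np.random.Generator, n: int):
        idx = rng.integers(0, len(pairs), size=n)
        p = np.array([pairs[i][0] for i in idx])
        q = np.array([pairs[i][1] for i in idx])
        return p, q

    return draw


def generate_sessions(
    n_sessions: int,
    game: GameConfig,
    strategy_source,
    seed: int,
    n_pairs_per_session: int = 9,
    endgame_dg: bool = False,
    dg_donations: Sequence[int] | None = None,
    history_statistic: str = "mean",
) -> pd.DataFrame:
    """Emulate the behavioural protocol of the matching experiment.

    Each session holds ``n_pairs_per_session`` dictators and as many
    receivers (default 9, i.e. 18 subjects) playing 30 rounds of random
    re-matching.  Rounds 1-3 are forced standard-DG play that seed each
    dictator's reputation — the rolling list of their last three accepted
    donations.  From round 4 on, the receiver is informed about her
    partner's history with probability ``game.omega``; when informed she
    accepts iff the history statistic (mean of the three recorded amounts,
    or the last one if ``history_statistic='last'``) meets her threshold
    ``q``, when uninformed iff the baseline ``q0`` does.  Rejection pays
    both zero and leaves the history unchanged.  If ``endgame_dg`` is set,
    dictators revert to a plain-DG donation in the final round (the
    strategic-generosity signature); ``dg_donations`` supplies those
    amounts, defaulting to the minimum donation.

    ``strategy_source`` is either a callable ``(rng, n) -> (p_array,
    q_array)`` or a sequence of (p, q) pairs sampled uniformly.

    Returns a tidy table with one row per (session, round, pair); the
    ``history`` column snapshots the reputation shown to the receiver as a
    '|'-joined string.
    """
    if n_sessions < 1 or n_pairs_per_session < 1:
        raise ValueError("need at least one session and one pair")
    if history_statistic not in ("mean", "last"):
        raise ValueError(f"unknown history statistic {history_statistic!r}")
    draw = _as_source(strategy_source)
    rng = np.random.default_rng(seed)
    rows = []
    for session in range(1, n_sessions + 1):
        n = n_pairs_per_session
        p_strat, q_strat = draw(rng, n)
        p_strat = np.asarray(p_strat, dtype=int)
        q_strat = np.asarray(q_strat, dtype=int)
        if np.any((p_strat < game.p_min) | (p_strat > game.p_max)):
            raise ValueError("strategy source produced donations out of range")
        if game.variant is not Variant.DG and np.any(
            (q_strat < 1) | (q_strat > game.q_max)
        ):
            raise ValueError("strategy source produced thresholds out of range")
        histories: list[list[int]] = [[] for _ in range(n)]
        for rnd in range(1, N_ROUNDS + 1):
            receiver_of = rng.permutation(n)
            for d in range(n):
                r = int(receiver_of[d])
                donation = int(p_strat[d])
                if endgame_dg and rnd == N_ROUNDS:
                    donation = (
                        int(dg_donations[d]) if dg_donations is not None else game.p_min
                    )
                hist_snapshot = "|".join(str(h) for h in histories[d])
                if rnd <= N_INITIATION_ROUNDS or game.variant is Variant.DG:
                    informed = False
                    accepted = True
                else:
                    informed = bool(rng.random() < game.omega)
                    if informed:
                        h = histories[d]
                        stat = (
                            float(np.mean(h))
                            if history_statistic == "mean"
                            else float(h[-1])
                        )
                    else:
                        stat = float(game.q0)
                    accepted = stat >= q_strat[r]
                if accepted:
                    d_pay, r_pay = game.endowment - donation, donation
                    histories[d].append(donation)
                    if len(histories[d]) > HISTORY_LENGTH:
                        histories[d].pop(0)
                else:
                    d_pay, r_pay = 0, 0
                rows.append(
                    (
                        session,
                        rnd,
                        d,
                        d,
                        r,
                        informed,
                        donation if accepted else pd.NA,
                        accepted,
                        d_pay,
                        r_pay,
                        hist_snapshot,
                    )
                )
    table = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    table["donation"] = table["donation"].astype("Int64")
    return table


def session_summaries(table: pd.DataFrame) -> dict:
    """Summary statistics of a session table.

    Pooled and per-session mean accepted donation, post-initiation
    acceptance rate, per-round mean donation series, the donation
    histogram, and the informed/uninformed donation split.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty session table")
    played = table[table["accepted"]]
    post = table[table["round"] > N_INITIATION_ROUNDS]
    per_session = (
        table.groupby("session")
        .apply(
            lambda g: pd.Series(
                {
                    "mean_donation": g.loc[g["accepted"], "donation"].astype(float).mean(),
                    "acceptance_rate": g.loc[
                        g["round"] > N_INITIATION_ROUNDS, "accepted"
                    ].mean(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    hist = (
        played["donation"].astype(int).value_counts().sort_index().to_dict()
    )
    informed_played = post[post["accepted"]].copy()
    if len(informed_played):
        informed_played["donation"] = informed_played["donation"].astype(float)
        by_informed = informed_played.groupby("informed")["donation"].mean()
    else:
        by_informed = pd.Series(dtype=float)
    return {
        "mean_donation": float(played["donation"].astype(float).mean()),
        "acceptance_rate": float(post["accepted"].mean()) if len(post) else 1.0,
        "per_session": per_session,
        "per_round_mean": played.groupby("round")["donation"]
        .mean()
        .astype(float)
        .to_dict(),
        "donation_histogram": hist,
        "mean_donation_by_informed": {
            bool(k): float(v) for k, v in by_informed.items()
        },
    }
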