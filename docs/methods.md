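# Methods

## Stage games and acceptance semantics

The endowment is X = 10 ECU and donations are integers p ∈ [p_min, X] with
p_min = 1: allowing p = 0 would create a second subgame perfect equilibrium
in which the receiver is indifferent between playing and not playing, so
the minimum donation is part of the game definition, not a numerical
convenience.  Receiver thresholds are integers q ∈ [1, q_max].  Two model
families are supported: the *basic* receiver space q_max = X, and the
*restricted* space q_max = 5, motivated by the observation that donations
of at least half the endowment are always accepted in the behavioural
data.  The DG is implemented as its own variant with a trivial receiver
(strategy set = {play}), not as the ω = 0 limit of the AG: with a positive
baseline expectation, ω = 0 would still reject low donations, which the DG
cannot.

Partial information (ω < 1) has two defensible readings, both implemented
behind `acceptance_mode`:

- `THRESHOLD_MIX` (default): the receiver's effective expectation is the
  convex combination ω·q + (1 − ω)·q₀ and she accepts iff p meets it.
  This is the literal "weighted combination of expectations".
- `BERNOULLI_MIX`: an information coin flip each round — with probability
  ω she applies q, otherwise q₀ — giving the acceptance probability
  ω·1[p ≥ q] + (1 − ω)·1[p ≥ q₀].

The two coincide exactly at ω ∈ {0, 1} (asserted by test).  Ties accept:
"expects at least q" means p ≥ threshold.  The baseline q₀ defaults to
2 ECU — the DG treatment average (≈ 2.2) rounded to the nearest feasible
donation — and is configurable.

A consequence worth flagging: with q₀ = 2 and ω = 0.5 the effective
threshold is at least 1.5 ECU, so a 1-ECU donation is *never* accepted in
the noisy AG.  Strong selection therefore concentrates the noisy AG on
p = 2 (the smallest donation an uninformed receiver accepts) rather than
on the 1-ECU subgame perfect donation of the fully informed AG.  The test
suite asserts exactly this.

## Evolutionary dynamics

Each population (dictators; receivers) holds N = 100 individuals; games
are always played across populations, evolution happens within them, and
players never switch roles.  Imitation follows the pairwise comparison
rule with the Fermi probability [1 + exp(−β(f_other − f_self))]⁻¹.

Because all payoffs come from the opposite population, a strategy's payoff
does not depend on its abundance in its own population.  The
ratio T⁻/T⁺ = exp(−β Δf) is then constant across interior states and the
fixation probability of a single mutant collapses to the geometric closed
form ρ = (1 − γ)/(1 − γᴺ) with γ = exp(−β Δf), ρ = 1/N at γ = 1.  The
general sum-of-products formula is retained as an independent oracle in
the tests (log-domain evaluation, agreement to 1e-12 relative).  Numerical
edges: the expm1 form is used for moderate arguments; for Nβ|Δf| > 700 the
disfavoured branch returns exp((N−1)βΔf), which underflows to zero
harmlessly.

In the rare-mutation limit the embedded Markov chain runs over the
|S_D| · |S_R| homogeneous states.  A mutant arises in either population
with weight w_D = w_R = 1/2 and is any of the other strategies of that
population with equal probability; the diagonal absorbs the remaining
mass.  Rescaling the weight split only moves mass to the diagonal and
leaves the stationary law unchanged (asserted by test).  The stationary
distribution is the eigenvector of Mᵀ at eigenvalue 1; if more than one
eigenvalue lies within 1e-9 of 1 the solver fails loudly rather than pick
a branch, and a power-iteration fallback guards against a numerically poor
eigenvector.  Residual tolerance: max|πM − π| ≤ 1e-8 (observed ≤ 1e-12).

β grids default to 60 logarithmic points between 1e-4 and 10, which spans
neutral drift (uniform stationary law, mean donation 5.5) to effectively
deterministic imitation (all mass on the minimal accepted donation).

## Anticipatory fitness and the self-consistent solve

The extension weights the dictator's current payoff against the payoff of
the next round, which is only realised if the *next* (randomly re-matched)
receiver accepts a dictator with donation p on record:

    f_D(p) = a_now · [ (1 − δ)(X − p) + δ (X − p) A(p) ]

where a_now is the current acceptance probability (0/1 under full
information) and A(p) the population-level acceptance curve.  Rejection
zeroes present *and* future, hence the overall a_now factor.  δ = 0
recovers the basic model bit-for-bit (asserted); δ = 1 makes success
purely prospective.

With monomorphic resident receivers and ω = 1, A(p) would be 0/1 and δ
would be inert, so A(p) is defined as the acceptance frequency under the
*stationary receiver marginal* of the coupled system, found by fixed-point
iteration: solve the chain given A, recompute A from the receiver
marginal, update with damping 0.5, stop when the sup-norm change drops
below 1e-8 (at most 200 iterations; typical runs converge in 20–70).  The
initial curve comes from a uniform receiver population; a one-shot
uniform-receiver baseline is available behind `self_consistent=False`.

Uniqueness is *not* claimed.  In the weak-to-moderate selection regime
(β ≲ 0.05–0.1, which covers the experimentally calibrated region
β ≈ 0.005–0.02) random initial curves all converge to the same fixed
point (asserted by a seeded multi-start test).  At strong selection with
large δ the coupled system is multistable — e.g. at δ = 1 a fixed point
exists where dictators sit at the maximiser of (X − p)A(p) over a spread
receiver population — and the mean donation is no longer monotone in β:
it plateaus near 4 ECU from β ≈ 0.07 upward.  The solver reports the
branch reached from the uniform start; monotonicity checks in the tests
are therefore restricted to the regime where the fixed point is unique.

## Calibration

Mean stationary donation is a decreasing function of β in the basic model,
so fitting an experimental average reduces to a bracketed bisection
(geometric midpoints on the log axis) stopping at 0.05 ECU on the mean —
the targets are printed to one decimal — or a relative bracket width of
1e-3.  Targets outside the attainable range raise an error reporting that
range.  The packaged targets are the printed treatment averages
(2.2 / 4.2 / 4.2 / 3.5 ECU) and acceptance rates (83% / 89%); they are
human-subject summaries used as fitting targets, never quantities the
model is claimed to derive.

## Monte Carlo simulator

The forward simulator runs the exact update rule with an explicit
per-update mutation probability μ: pick a population (1/2 each), a
learner; with probability μ adopt a uniformly random strategy of that
population (including possibly the same one, so μ is comparable across
strategy-set sizes), else imitate a distinct random role model via the
Fermi rule with payoffs averaged over the opposite population's current
composition.  While both populations are homogeneous an imitation update
cannot change anything, so the kernel draws the geometric waiting time to
the next mutation and credits the skipped occupancy in one step — an
exact acceleration, not an approximation, which is what makes the
μ = 1e-4 regime affordable (billions of virtual updates per minute of CPU).
Runs are bit-reproducible given the seed.

Agreement checks use N = 50 and μ = 1e-4 (μN = 5e-3 ≪ 1): total variation
against the embedded chain stays below 0.05 at weak (β = 0.01), fitted
(β = 0.05–0.1) and strong (β = 1) selection, with 0.5–8 × 10⁹ virtual
updates per run — sizes chosen so the sampling error of the fixation
events (the effective sample size of the occupancy estimate) sits well
inside the 0.05 band.

## Synthetic sessions

The session generator emulates the behavioural protocol, not human
behaviour: 9 dictator/receiver pairs per session (18 subjects), 30 rounds
of uniform random re-matching, rounds 1–3 forced standard-DG play seeding
each dictator's 3-donation rolling history, information flips at rate ω,
and histories frozen on rejected rounds.  The informed receiver compares
her threshold to the *mean* of the visible history by default ("last"
mode available) and to q₀ when uninformed.  With `endgame_dg` dictators
revert to a plain-DG donation in round 30, reproducing the last-round
defection signature of strategic generosity.

Because strategies are sampled i.i.d. from a supplied source (e.g. a
stationary distribution) and held fixed within a session, the generator
exercises bookkeeping and summary code; it does not model within-session
learning, payment conversion, or the refusal-count information of the
third treatment.  Passing tests on these sessions validate the protocol
plumbing and summary statistics, not behavioural realism.

## Known limitations

- The embedded chain is the μ → 0 limit; non-vanishing mutation rates are
  available only through the Monte Carlo simulator.
- δ is a system-level parameter, not an evolving individual trait.
- The noisy AG treats the baseline expectation q₀ as homogeneous across
  receivers.
- Multistability of the anticipatory fixed point at strong selection means
  reported values there are start-dependent (uniform start by convention).
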