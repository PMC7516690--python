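# Methods

## The model

Each subject's daily medication record is a binary series x_1, ..., x_T with
x_t = 1 when an ingestion was observed on day t and x_t = 0 otherwise.  The
series is treated as a first-order, two-state Markov chain.  From the
transition counts n_qr (the number of adjacent day pairs q -> r, with
q, r in {0, 1}) the transition probabilities are estimated by maximum
likelihood,

    p_qr = n_qr / (n_q0 + n_q1),

the stationary distribution pi is the left unit eigenvector of the
transition matrix P (computed by eigendecomposition, normalised to sum 1),
and the entropy rate of the chain is

    H = - sum_q pi_q sum_r p_qr ln p_qr        (nats; 0 * ln 0 := 0).

H lies in [0, ln 2] for a two-state chain, is 0 for deterministic behavior
(all-ones, perfect alternation) and ln 2 only for the fair-coin chain.
*Adherence volatility* is the trajectory of H as the chain is re-estimated
each day from all data observed so far.  The natural logarithm is canonical
throughout; no smoothing is applied to the ML estimates.

The approach assumes stationarity and irreducibility, neither of which can
be verified on 60-day series; the detection step is deliberately contextual
(changes relative to the subject's own history) so that accurate point
estimation of H is not required.

## Contextual anomaly detection

After an initialization period of `init_days` (default 10), the remaining
days are tiled into observation windows of `window_days` (default 5; the
final window may be shorter — it is evaluated over the 2^m futures of its m
remaining days rather than dropped).  The defaults evenly divide a 30-day
treatment cycle.  For each window:

1. All 2^n possible n-day continuations of the history are enumerated.
   Each continuation's weight is the product of one-step transition
   probabilities under the matrix **frozen at the window start** (the
   matrix is not updated inside the hypothetical continuation); the
   terminal entropy is H re-estimated from history + continuation in full.
2. The expectation band is the weighted mean of the terminal entropies
   +/- `sd_multiplier` (default 1) times the weighted population SD (no
   bias correction; weights already sum to 1).
3. The band is held fixed across the window.  The observed daily trace —
   H computed from *all* data up to each day, not window-local — is
   compared against it; the window is a **behavioral anomaly** if the trace
   strictly exits the band on any day.  Strict inequality means a
   zero-variance band exactly matched by deterministic behavior (e.g.
   uninterrupted successes) does not flag.
4. The observed days are appended to the history before the next window's
   band is computed, so an anomaly in one period reshapes the expectations
   for the next.  This is what makes a once-seen pattern unremarkable when
   it recurs (asserted on a concrete fixture in the test suite).

A **behavioral shift** is a maximal run of at least two consecutive
anomalous windows.  Flagged windows are labelled `success_driven` when the
observed number of 1s strictly exceeds the weighted expected number of 1s
under the enumerated futures, `miss_driven` when strictly below, and
`undetermined` on a tie; unflagged windows carry `undetermined` since the
classification is only meaningful for anomalies.  The excursion direction
(`above`/`below`/`mixed`) is recorded descriptively.

Subjects with fewer than `min_sequence_days` (default 11, i.e. more than 10
days of data) observations are marked ineligible and excluded from cohort
denominators; sequences too short to host a single window produce an
ineligible report rather than an exception.

## Degenerate inputs and numerical choices

- **Zero-count rows.** A state with no observed outgoing transitions is
  assigned self-transition probability 1 and flagged `row_defined=False`.
  This keeps the matrix row-stochastic and gives apparently-absorbing
  short histories zero entropy contribution.
- **Doubly-absorbing matrices** (e.g. from an all-ones history): the
  stationary law is not unique and is resolved as a point mass on the last
  observed state; the entropy rate is 0 either way.
- **A consequence worth knowing:** after a perfect run, a sudden total
  collapse ("1111111111" then "00000") estimates state 0 as absorbing, so
  the trace *stays at 0* inside the degenerate (0, 0) band and the collapse
  itself is not flagged; the detector fires as soon as a success reappears
  and breaks the absorbing illusion.  This is the faithful consequence of
  pure-ML estimation with the self-absorbing convention, not an oversight.
- **Eigenvector extraction:** the eigenvalue nearest 1 must lie within
  1e-8; components are taken in absolute value before normalising by their
  sum, guarding eigenvector sign ambiguity.  Hot paths (the daily trace,
  the 2^n enumeration) run the same eigendecomposition batched over stacked
  2x2 matrices.
- **Trace start:** the entropy rate is emitted from day 2 (first observed
  transition); day 1 carries no value.
- Entropy values are clipped to [0, ln 2] to remove rounding noise at the
  boundaries; weights must renormalise to 1 within 1e-12.
- Enumeration is capped at window length 20 (2^20 futures) to bound cost.

## The simulator

The clinical event logs the method was developed on are not public.  The
simulator stands in for them with exactly the data-generating process the
estimator assumes: constant-parameter two-state chains.  Six presets cover
high and low long-run adherence (p_01/p_10 of .3/.1, .1/.5, .3/.5 twice,
.5/.1 and .1/.3) over 60-day horizons — the durations and parameter choices
of the illustrative scenarios — with the initial state drawn from the
stationary law by default (fixed-state rules exist for fixture
construction).  The long-run success rate of each preset follows from the
closed form p_01/(p_01+p_10): 0.75, 0.17, 0.38, 0.38, 0.83 and 0.25.
`synthetic_cohort` mixes presets into reproducible multi-subject
cohorts with child seeds drawn from one root seed.

What the simulator does *not* emulate — and therefore what passing tests do
not establish about clinical data: drifting transition structure over
treatment, device non-compliance masquerading as missed doses, multiple
ingestions per day, and dropout.  Detection results on simulated chains
show the method's behavior under its own assumptions, including the point
that constant-parameter chains still produce contextual anomalies.

## Problem sizes in the test suite

The suite verifies the closed-form stationary/entropy agreement on 10,000
random matrices, Monte-Carlo agreement of the expectation bands on 20
seeded histories at 100,000 sampled continuations each, parameter recovery
on 10,000-day simulations for all six presets, stationary convergence at
200,000 days, exhaustive shift extraction on all flag patterns up to length
8, and anomaly occurrence over 1,000 seeded 60-day runs per preset.  These
sizes make the statistical assertions sharp at 3-standard-error tolerances
while keeping the whole suite around a minute.

## Design choices that were genuinely open

- **Fixed band per window vs. per-day re-enumeration:** the band is built
  once per window from the distribution of *end-of-window* entropy rates
  and held constant; the observed trace is checked daily against it.  The
  alternative (2^t prefix enumeration per day inside the window) is a
  possible extension, not implemented.
- **Driver rule:** the green/red classification is operationalised as the
  observed-vs-expected success-count comparison described above; the source
  analyses never specify their rule.
- **Day gaps in event logs** are rejected by default; the
  `fill_missing_as_zero` option adopts the convention that an unrecorded
  day is an unobserved ingestion, which is appropriate for sensor-derived
  data where absence of signal *is* the 0 state.

## Limitations

Anomalies and shifts are statistical statements about a subject's own
history, not clinical findings; the band construction characterises only
the first two weighted moments of the terminal entropy distribution; and
with ±1 SD bands, skewed future distributions flag readily — on simulated
60-day chains a typical run shows several anomalous windows, so shift
counts, not single anomalies, are the more robust signal.
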