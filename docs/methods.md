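# Methods

## The model class

A motif model is a statechart of a deliberately restricted shape: one
parallel composite containing, for every component (gene or signal), one
two-state exclusive machine with states *off* and *on*. No deeper hierarchy,
no events or actions on transitions, no history connectors — the fragment is
exactly what is needed for boolean motif dynamics, and nothing deeper is
representable on purpose, which keeps the semantics unambiguous.

A regulated component's two transitions carry a guard pair: the off→on
transition fires when the on-guard holds, the on→off transition when the
off-guard holds, both evaluated on the *previous* instant's full
configuration (synchronous update). We construct rules from a next-state
function *f* as (on-guard = *f*, off-guard = ¬*f*). This complementarity is
a modeling choice the package enforces: the guard pair is then total and
exclusive, the dynamics is a deterministic boolean network, and the behavior
is defined in every configuration — including when the regulator is absent,
the situation that makes partially-specified two-guard models incomplete.
Validation checks the pair exhaustively over the guards' variables (state
spaces here never exceed 2^6, so exhaustive checking is exact and cheap).

An escape hatch `make_model(..., allow_partial=True)` admits guard pairs
with *gaps*, giving hold-state semantics when neither guard fires; it exists
for experimentation and no shipped motif uses it. Guard *overlap* — both
guards true on some assignment — is a hard validation error in either mode,
with a witness assignment in the message: silently tie-breaking a
simultaneous on/off firing would hide nondeterminism.

Independent components (gene X in the feedforward loops, all signals in
every shipped motif) carry no rule. They change only through input schedule
events; the synchronous step holds them constant.

## Timing convention

Schedule events take effect **at** their instant: the state at instant *t*
is overlaid with the events at *t* before the step to *t*+1 is computed. An
input switched on at *t*=2 is therefore visible in the trace at *t*=2 and
first affects its direct targets at *t*=3, and indirect targets (through one
intermediate gene) at *t*=4. This is the only convention consistent with the
reference diagrams of the feedforward loop, which show the input bar change,
the intermediate response, and the output response on three consecutive
instants. Traces start at instant 0 by default; `start` (CLI `--start`)
relabels the axis when a different origin is wanted — since the reference
events are anchored at *t*=2 by the schedule itself, the origin is a pure
labeling matter.

## The motif catalogue

All builders use canonical names X, S_X, Y, S_Y, Z and ship with
presence-mediated signals (absence-mediated variants are expressible through
the generic model constructor by negating the signal literal).

- **Simple regulation s1–s4**: next(Y) = X∧S_X (s1), ¬(X∧¬S_X) (s2),
  ¬(X∧S_X) (s3), X∧¬S_X (s4). The s2/s4 functions are *inferred* from the
  motif definitions (repression of Y exactly when X acts without / with its
  signal); the reference figures print them only graphically. The four
  next-state tables are pairwise distinct — the catalogue is non-ambiguous,
  and a test asserts it.
- **Feedback loops**: both X and Y regulated, signals independent.
  Double-positive: next(X)=Y∧S_Y, next(Y)=X∧S_X. Double-negative: both
  negated. Negative: next(X)=Y∧S_Y, next(Y)=¬(X∧S_X).
- **Feedforward loops c1/i1**: next(Y)=X∧S_X; the Z-gate combines the input
  branches X∧S_X and (for c1) Y∧S_Y or (for i1) ¬(Y∧S_Y) with AND or OR.
  Gating each branch by its gene's own signal is the active-regulator
  convention; it is the composition that reproduces the reference
  activation/deactivation timings.
- **Autoregulation**: next(Y)=Y (positive, lock-in) or ¬Y (negative,
  alternation). With an activating gene X the rule becomes X∧Y or X∧¬Y;
  whether X's action is itself signal-mediated is not fixed by the source
  material, so the shipped form uses plain X and a `signal_gated` keyword
  adds S_X mediation for symmetry (default off).

## Analyses

- **Attractor enumeration** brute-forces all 2^k configurations of the
  unclamped components, following the step map to its first revisit. Exact
  for these system sizes; a configurable cap (default 2^20 states) guards
  against accidentally huge models. Cycles are canonicalized by rotating to
  the lexicographically smallest state (component order) and the attractor
  list is sorted by that state, so output is reproducible and diffable.
  Basin sizes count enumerated initial states per attractor.
- **Bistability check**: verifies candidate steady-state pairs are fixed
  points under clamping and lists the initial states whose attractor is
  neither — for the feedback loops these are exactly the states trapped in
  the 2-cycle, the boolean-domain artifact that prevents convergence.
- **Oscillation period**: the smallest p for which a suffix of the trace is
  p-periodic, requiring at least one full witnessed repetition of the
  period; the transient prefix is dropped by this suffix analysis rather
  than a fixed burn-in, which is exact in finite deterministic systems and
  also behaves correctly on traces perturbed mid-way by schedule events.
  Period 1 means the trace settled to a fixed point.
- **Pulse detection** is a run-length scan; on-runs touching either trace
  boundary are flagged open-ended rather than counted as pulses, since the
  trace does not show them bounded.

## Serialization

The on-disk model format is a BoolNet-style rule file (`targets, factors`
header, `&`/`|`/`!` formulas), the closest community convention for boolean
GRN rules; it keeps models diffable and readable by other logical-modeling
tools. The dialect has no notion of an exogenous input, so independent
components are written as self-holding rules plus an `# independent:` marker
comment (and signals as `# signal:`), which makes the round-trip exact —
a property test checks table-identity on the whole catalogue and on 100
randomly generated valid models. Statechart structure exports to Graphviz
DOT (one cluster per component, guard-labeled edges) and SCXML (one
`<parallel>`, guards as transition `cond` attributes); both are write-only —
executing third-party SCXML engines is out of scope.

## Determinism and scale

There is no randomness anywhere in the system: equal inputs give identical
traces, and the CLI deliberately has no `--seed`. All reference behaviors
live in state spaces of at most 32 states and horizons of at most a dozen
instants; the full test suite and the acceptance script each run in
seconds. The random models used by round-trip property tests come from a
seeded generator in the test suite (4 components, random guard trees of
depth ≤ 2).

## Known limitations

The boolean domain is coarse by construction: damped oscillation, response
acceleration/deceleration (the quantitative signatures of autoregulation and
of the i1 FFL relative to simple regulation), and any behavior needing more
than two expression levels cannot be represented. Asynchronous and
stochastic update schemes are out of scope — all analyses assume the
synchronous semantics. The feedback-loop 2-cycles from disagreeing (or
agreeing) initial states are artifacts of that synchrony, not biology: real
toggle switches escape to a steady state through noise and unequal rates.
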