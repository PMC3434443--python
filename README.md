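# motifchart

Executable statechart models of gene regulatory network (GRN) motifs.

Small recurring interaction patterns — *motifs* — appear in real gene
regulatory networks far more often than chance predicts: simple regulation,
feedback loops, feedforward loops, autoregulation. `motifchart` models each
motif as a parallel composition of two-state (off/on) machines, one per gene
or signal, whose transitions are guarded by boolean formulas over the
presence of the other components. Under the synchronous discrete-time
semantics (every regulated gene recomputes its state at instant *t*+1 from
the full configuration at instant *t*) each motif is a small deterministic
boolean network, so its dynamics can be analyzed exactly: traces, attractors
with basins, and the motifs' signature temporal properties.

The package is for systems biologists and students of logical GRN modeling
who want a precise, scriptable version of the classic motif behaviors:

- **sign-sensitive delay** of the coherent type-1 feedforward loop (c1 FFL):
  output activation is delayed by one step behind the intermediate gene, but
  deactivation is immediate;
- the **unit pulse** of the incoherent type-1 FFL (i1 FFL);
- **joint / exclusive bistability** of the double-positive / double-negative
  feedback loops, including the boolean artifact that disagreeing (resp.
  agreeing) initial states stay trapped in a 2-cycle;
- the **period-4 oscillation** of the negative feedback loop;
- the **lock-in** of positive autoregulation and the alternation of negative
  autoregulation.

## Model

Each regulated gene carries an update rule: a guard pair
(on-guard *f*, off-guard ¬*f*) derived from a next-state function *f*, e.g.
for the c1 FFL with AND gate

```
next(Y) = X ∧ S_X
next(Z) = (X ∧ S_X) ∧ (Y ∧ S_Y)
```

where S_X, S_Y are the mediating signals. Components without a rule are
*independent*: nothing inside the motif changes them; they are driven only by
timed input events (an `InputSchedule`). Events take effect *at* their
instant: the state at *t* already shows the event applied, so an input
appearing at *t*=2 first affects its direct targets at *t*=3.

## Worked example

```python
from motifchart import build_ffl, simulate, InputSchedule, first_on_time

model = build_ffl("c1")                       # X, S_X, Y, S_Y, Z
initial = {"X": 0, "S_X": 1, "Y": 0, "S_Y": 1, "Z": 0}
trace = simulate(model, initial, InputSchedule(((2, "X", 1),)), horizon=8)
print(trace.to_dataframe().to_string(index=False))
print("Y first on at", first_on_time(trace, "Y"))
print("Z first on at", first_on_time(trace, "Z"))
```

prints

```
 t  X  S_X  Y  S_Y  Z
 0  0    1  0    1  0
 1  0    1  0    1  0
 2  1    1  0    1  0
 3  1    1  1    1  0
 4  1    1  1    1  1
 5  1    1  1    1  1
 6  1    1  1    1  1
 7  1    1  1    1  1
Y first on at 3
Z first on at 4
```

X appears at instant 2; the intermediate gene Y responds one step later at
instant 3, and the output Z — which needs both X and Y active — only in the
step after that, at instant 4. That one-step lag behind Y is the delayed
branch of the sign-sensitive delay; repeating the run from the all-on state
with X switched *off* at instant 2 shows Y and Z both off already at
instant 3 (no deactivation delay).

The same runs from the shell:

```
motifchart simulate ffl-c1 --clamp S_X=1,S_Y=1 --event t=2:X=1 --horizon 8
motifchart attractors feedback-dp --clamp S_X=1,S_Y=1
motifchart check pulse ffl-i1 --clamp S_X=1,S_Y=1 --event t=2:X=1
motifchart build ffl-i1 -o i1.bnet
motifchart export ffl-c1 --format scxml
```

Models are serialized as BoolNet-style `.bnet` rule files (read/write),
traces as CSV, and statechart structure as Graphviz DOT or SCXML
(write-only). `check` subcommands emit YAML verdicts and exit with code 1
when the property fails, 2 on usage or validation errors.

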