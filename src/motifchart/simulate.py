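"""Synchronous execution, attractor enumeration and temporal-property checks.

The dynamics is the synchronous boolean-network semantics of the motif
statecharts: at every time instant all regulated components recompute
their state simultaneously from the full configuration at the previous
instant, while independent components hold their value unless an input
schedule event overrides them.  Events take effect *at* their instant —
the state at instant t already shows the event applied — which is the
convention under which an input appearing at t=2 first affects its direct
targets at t=3.

Everything here is deterministic and exhaustive; state spaces are tiny
(2**k for k components), so attractors and basins are found by brute-force
iteration of the step map from every initial configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .model import MotifModel
from .logic import eval_formula

__all__ = [
    "InputSchedule",
    "Trace",
    "Attractor",
    "Pulse",
    "BistabilityReport",
    "PairVerdict",
    "SimulationError",
    "PartialConfigurationError",
    "ScheduleError",
    "StateSpaceTooLargeError",
    "step",
    "simulate",
    "enumerate_attractors",
    "first_on_time",
    "detect_pulses",
    "check_bistability",
    "oscillation_period",
]


class SimulationError(ValueError):
    pass


class PartialConfigurationError(SimulationError):
    def __init__(self, missing: Sequence[str]):
        super().__init__(f"configuration is missing components: {sorted(missing)}")
        self.missing = tuple(missing)


class ScheduleError(SimulationError):
    pass


class StateSpaceTooLargeError(SimulationError):
    pass


@dataclass(frozen=True)
class InputSchedule:
    """Timed on/off events for independent components.

    Each event is ``(time, component, value)``: at time instant ``time``
    the named component is set to ``value`` (0 or 1).  At most one event
    per (time, component) pair; whether the targets are independent in a
    given model is checked by :func:`simulate`.
    """

    events: tuple[tuple[int, str, int], ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for time, component, value in self.events:
            if time < 0:
                raise ScheduleError(f"negative event time {time} for {component!r}")
            if value not in (0, 1):
                raise ScheduleError(
                    f"event value for {component!r} at t={time} must be 0 or 1, "
                    f"got {value!r}"
                )
            key = (time, component)
            if key in seen:
                raise ScheduleError(
                    f"duplicate event for component {component!r} at t={time}"
                )
            seen.add(key)

    def events_at(self, time: int) -> dict[str, int]:
        return {c: v for (t, c, v) in self.events if t == time}

    @property
    def components(self) -> frozenset[str]:
        return frozenset(c for (_, c, _) in self.events)

    @property
    def max_time(self) -> Optional[int]:
        return max((t for (t, _, _) in self.events), default=None)


@dataclass(frozen=True)
class Trace:
    """A time-indexed sequence of configurations.

    ``configs[k]`` is the (total) configuration at instant ``start + k``.
    Column/component order follows the model's component order.
    """

    model_name: str
    components: tuple[str, ...]
    configs: tuple[dict, ...]
    start: int = 0

    def __post_init__(self) -> None:
        if len(self.configs) < 1:
            raise ValueError("a trace has at least one configuration")

    def __len__(self) -> int:
        return len(self.configs)

    @property
    def instants(self) -> range:
        return range(self.start, self.start + len(self.configs))

    def values(self, component: str) -> tuple[int, ...]:
        """The 0/1 series of one component, raising on unknown names."""
        if component not in self.components:
            raise KeyError(
                f"component {component!r} not in trace (has {self.components})"
            )
        return tuple(c[component] for c in self.configs)

    def at(self, instant: int) -> dict:
        return self.configs[instant - self.start]

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: one row per instant, columns ``t`` plus components."""
        rows = [
            {"t": t, **{name: cfg[name] for name in self.components}}
            for t, cfg in zip(self.instants, self.configs)
        ]
        return pd.DataFrame(rows, columns=["t", *self.components])


@dataclass(frozen=True)
class Attractor:
    """A fixed point or cycle of the synchronous step map.

    ``states`` lists the cycle in step order starting from its
    lexicographically smallest member (component order); ``basin_size``
    counts the enumerated initial states that reach it.
    """

    states: tuple[dict, ...]
    kind: str  # "fixed_point" | "cycle"
    basin_size: int = 0

    @property
    def period(self) -> int:
        return len(self.states)


class Pulse(NamedTuple):
    """A maximal run of consecutive on-instants of one component.

    A run that touches either end of the trace is flagged ``open_ended``:
    the trace does not show it bounded by off-states, so it is not counted
    as a pulse proper.
    """

    start: int
    width: int
    open_ended: bool = False


def _require_total(model: MotifModel, config: Mapping[str, int]) -> None:
    missing = [n for n in model.component_names if n not in config]
    if missing:
        raise PartialConfigurationError(missing)


def step(model: MotifModel, config: Mapping[str, int]) -> dict:
    """One synchronous update; the input configuration is not modified.

    Every regulated component becomes 1 if its on-guard holds on
    ``config``, 0 if its off-guard holds, and keeps its value if neither
    fires (only possible for partial-guard models).  Independent
    components keep their value.
    """
    _require_total(model, config)
    nxt: dict = {}
    for comp in model.components:
        if comp.rule is None:
            nxt[comp.name] = config[comp.name]
        elif eval_formula(comp.rule.on_guard, config):
            nxt[comp.name] = 1
        elif eval_formula(comp.rule.off_guard, config):
            nxt[comp.name] = 0
        else:
            nxt[comp.name] = config[comp.name]
    return nxt


def simulate(
    model: MotifModel,
    initial: Mapping[str, int],
    schedule: InputSchedule | None = None,
    horizon: int = 1,
    *,
    start: int = 0,
) -> Trace:
    """Run the synchronous dynamics for ``horizon`` instants.

    The state at instant t is first overlaid with all schedule events at
    time t, then one step produces the state at t+1, which is overlaid
    with the events at t+1, and so on.  The trace therefore shows every
    event already applied at its own instant.

    Raises
    ------
    ScheduleError
        If an event targets a regulated component, an unknown component,
        or a time outside ``[start, start + horizon)``.
    """
    if horizon < 1:
        raise SimulationError(f"horizon must be >= 1, got {horizon}")
    _require_total(model, initial)
    schedule = schedule or InputSchedule()
    independent = set(model.independent_names())
    for time, component, _ in schedule.events:
        if component not in model.component_names:
            raise ScheduleError(f"schedule targets unknown component {component!r}")
        if component not in independent:
            raise ScheduleError(
                f"schedule targets regulated component {component!r}; only "
                "independent components accept input events"
            )
        if not (start <= time < start + horizon):
            raise ScheduleError(
                f"event time {time} outside simulated window "
                f"[{start}, {start + horizon})"
            )
    state = {n: int(initial[n]) for n in model.component_names}
    state.update(schedule.events_at(start))
    configs = [dict(state)]
    for k in range(1, horizon):
        state = step(model, state)
        state.update(schedule.events_at(start + k))
        configs.append(dict(state))
    return Trace(
        model_name=model.name,
        components=model.component_names,
        configs=tuple(configs),
        start=start,
    )


def _state_key(model: MotifModel, config: Mapping[str, int]) -> tuple[int, ...]:
    return tuple(config[n] for n in model.component_names)


def _explore(
    model: MotifModel,
    clamped: Mapping[str, int],
    max_states: int,
) -> tuple[list[Attractor], dict[tuple[int, ...], int]]:
    """Brute-force the state space under clamping.

    Returns the canonically ordered attractor list and a map from every
    enumerated initial state (as a value tuple in component order) to the
    index of the attractor it falls into.
    """
    names = model.component_names
    independent = set(model.independent_names())
    for c in clamped:
        if c not in names:
            raise SimulationError(f"clamped component {c!r} not in model")
        if c not in independent:
            raise SimulationError(
                f"clamped component {c!r} is regulated; only independent "
                "components can be clamped"
            )
    free = [n for n in names if n not in clamped]
    if 2 ** len(free) > max_states:
        raise StateSpaceTooLargeError(
            f"{2 ** len(free)} states exceeds the cap of {max_states}"
        )

    raw_cycles: list[tuple[tuple[int, ...], ...]] = []
    cycle_index: dict[tuple[int, ...], int] = {}  # state on a cycle -> cycle id
    basin_of: dict[tuple[int, ...], int] = {}

    for bits in itertools.product((0, 1), repeat=len(free)):
        config = dict(zip(free, bits))
        config.update(clamped)
        path: list[tuple[int, ...]] = []
        seen_at: dict[tuple[int, ...], int] = {}
        key = _state_key(model, config)
        while key not in cycle_index and key not in seen_at:
            seen_at[key] = len(path)
            path.append(key)
            config = step(model, dict(zip(names, key)))
            key = _state_key(model, config)
        if key in cycle_index:
            cid = cycle_index[key]
        else:
            # new cycle discovered on this path
            cycle = tuple(path[seen_at[key]:])
            cid = len(raw_cycles)
            raw_cycles.append(cycle)
            for s in cycle:
                cycle_index[s] = cid
        basin_of[key] = cid
        for s in path:
            basin_of[s] = cid

    # canonicalize: rotate each cycle to start at its lexicographic minimum,
    # then sort attractors by that minimum
    canon: list[tuple[tuple[int, ...], ...]] = []
    for cycle in raw_cycles:
        i = cycle.index(min(cycle))
        canon.append(cycle[i:] + cycle[:i])
    order = sorted(range(len(canon)), key=lambda i: canon[i][0])
    remap = {old: new for new, old in enumerate(order)}

    basin_counts = [0] * len(canon)
    basin_of_final: dict[tuple[int, ...], int] = {}
    for state, cid in basin_of.items():
        basin_of_final[state] = remap[cid]
        basin_counts[remap[cid]] += 1

    attractors = [
        Attractor(
            states=tuple(dict(zip(names, s)) for s in canon[old]),
            kind="fixed_point" if len(canon[old]) == 1 else "cycle",
            basin_size=basin_counts[remap[old]],
        )
        for old in order
    ]
    return attractors, basin_of_final


def enumerate_attractors(
    model: MotifModel,
    clamped: Mapping[str, int] | None = None,
    *,
    max_states: int = 2**20,
) -> list[Attractor]:
    """All attractors of the synchronous dynamics under clamping.

    Iterates every configuration of the unclamped components, follows the
    step map until a state repeats, and collects the distinct fixed points
    and cycles together with their basin sizes.  Attractors are sorted by
    their lexicographically smallest member state (component order), and
    cycles are rotated to start at that state.
    """
    attractors, _ = _explore(model, dict(clamped or {}), max_states)
    return attractors


def first_on_time(trace: Trace, component: str) -> Optional[int]:
    """Smallest instant at which the component is on, or None if never."""
    for t, v in zip(trace.instants, trace.values(component)):
        if v == 1:
            return t
    return None


def detect_pulses(trace: Trace, component: str) -> list[Pulse]:
    """Maximal on-runs of one component, boundary runs flagged open-ended.

    A pulse proper is a run of 1s preceded and followed by a 0 within the
    trace; runs touching the first or last instant are returned with
    ``open_ended=True`` since the trace does not bound them.
    """
    values = trace.values(component)
    runs: list[Pulse] = []
    i = 0
    n = len(values)
    while i < n:
        if values[i] == 1:
            j = i
            while j < n and values[j] == 1:
                j += 1
            open_ended = i == 0 or j == n
            runs.append(Pulse(trace.start + i, j - i, open_ended))
            i = j
        else:
            i += 1
    return runs


class PairVerdict(NamedTuple):
    pair: tuple[dict, dict]
    first_fixed: bool
    second_fixed: bool

    @property
    def both_fixed(self) -> bool:
        return self.first_fixed and self.second_fixed


@dataclass(frozen=True)
class BistabilityReport:
    """Verdict of a bistability check.

    For each candidate pair of steady states the report says whether both
    are fixed points under the clamping; ``non_converging`` lists every
    enumerated initial state whose attractor is none of the pairs' fixed
    points — the states trapped in an oscillating pattern instead of
    settling into a steady state.
    """

    pairs: tuple[PairVerdict, ...]
    non_converging: tuple[dict, ...]

    @property
    def bistable(self) -> bool:
        return all(p.both_fixed for p in self.pairs)


def check_bistability(
    model: MotifModel,
    clamped: Mapping[str, int] | None = None,
    pairs: Iterable[tuple[Mapping[str, int], Mapping[str, int]]] = (),
) -> BistabilityReport:
    """Check candidate steady-state pairs and find non-converging states."""
    clamped = dict(clamped or {})
    attractors, basin_of = _explore(model, clamped, 2**20)

    def is_fixed(cfg: Mapping[str, int]) -> bool:
        _require_total(model, cfg)
        full = {n: int(cfg[n]) for n in model.component_names}
        return step(model, full) == full

    verdicts = []
    target_attr: set[int] = set()
    for a, b in pairs:
        fa, fb = is_fixed(a), is_fixed(b)
        verdicts.append(
            PairVerdict(
                pair=(
                    {n: int(a[n]) for n in model.component_names},
                    {n: int(b[n]) for n in model.component_names},
                ),
                first_fixed=fa,
                second_fixed=fb,
            )
        )
        for cfg, fixed in ((a, fa), (b, fb)):
            if fixed:
                key = _state_key(model, cfg)
                if key in basin_of:
                    target_attr.add(basin_of[key])

    names = model.component_names
    non_conv = tuple(
        dict(zip(names, state))
        for state, aid in sorted(basin_of.items())
        if aid not in target_attr
    )
    return BistabilityReport(pairs=tuple(verdicts), non_converging=non_conv)


def oscillation_period(trace: Trace) -> Optional[int]:
    """Eventual period of a trace, or None if it never becomes periodic.

    The transient prefix (everything before the trace first revisits a
    configuration and settles into repetition) is removed, and the
    smallest p >= 1 for which the remaining tail is p-periodic is
    returned.  A full repetition of the period must be witnessed inside
    the trace; 1 means the trace settled to a fixed point.
    """
    if len(trace) < 2:
        raise ValueError("oscillation_period needs a trace of length >= 2")
    keys = [tuple(sorted(c.items())) for c in trace.configs]
    n = len(keys)
    for p in range(1, n // 2 + 1):
        # longest suffix on which the trace is p-periodic
        s = n - p
        for i in range(n - p - 1, -1, -1):
            if keys[i] == keys[i + p]:
                s = i
            else:
                break
        if s <= n - 2 * p:
            return p
    return None
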