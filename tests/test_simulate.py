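"""Synchronous execution, schedules, attractors and temporal-property checks."""

import itertools

import pytest

from motifchart import (
    Component,
    InputSchedule,
    Pulse,
    ScheduleError,
    StateSpaceTooLargeError,
    Trace,
    build_autoregulation,
    build_feedback,
    build_ffl,
    build_named,
    check_bistability,
    detect_pulses,
    enumerate_attractors,
    first_on_time,
    make_rule_from_next_state,
    make_model,
    oscillation_period,
    simulate,
    step,
)
from motifchart.motifs import MOTIF_BUILDERS
from motifchart.simulate import PartialConfigurationError, _state_key

SIGNALS_ON = {"S_X": 1, "S_Y": 1}


def all_off(model, **overrides):
    config = {n: 0 for n in model.component_names}
    config.update({k: v for k, v in SIGNALS_ON.items() if k in config})
    config.update(overrides)
    return config


class TestStep:
    def test_negative_feedback_cycles_through_four_states(self):
        model = build_feedback("negative")
        config = all_off(model, X=1, Y=1)
        seen = [(config["X"], config["Y"])]
        for _ in range(4):
            config = step(model, config)
            seen.append((config["X"], config["Y"]))
        assert seen == [(1, 1), (1, 0), (0, 0), (0, 1), (1, 1)]

    def test_step_does_not_mutate_input(self):
        model = build_feedback("negative")
        config = all_off(model, X=1, Y=1)
        before = dict(config)
        step(model, config)
        assert config == before

    def test_independent_components_are_held(self):
        model = make_model([Component("A"), Component("B")])
        assert step(model, {"A": 1, "B": 0}) == {"A": 1, "B": 0}

    def test_partial_configuration_rejected(self):
        model = build_feedback("negative")
        with pytest.raises(PartialConfigurationError):
            step(model, {"X": 1})


class TestSimulate:
    def test_ffl_activation_delay(self):
        model = build_ffl("c1")
        trace = simulate(model, all_off(model), InputSchedule(((2, "X", 1),)), 8)
        assert first_on_time(trace, "Y") == 3
        assert first_on_time(trace, "Z") == 4

    def test_ffl_immediate_deactivation(self):
        model = build_ffl("c1")
        trace = simulate(
            model, all_off(model, X=1, Y=1, Z=1), InputSchedule(((2, "X", 0),)), 8
        )
        assert trace.at(3)["Y"] == 0 and trace.at(3)["Z"] == 0

    def test_i1_unit_pulse(self):
        model = build_ffl("i1")
        trace = simulate(model, all_off(model), InputSchedule(((2, "X", 1),)), 8)
        assert trace.values("Z") == (0, 0, 0, 1, 0, 0, 0, 0)

    def test_event_takes_effect_at_its_own_instant(self):
        model = build_ffl("c1")
        trace = simulate(model, all_off(model), InputSchedule(((2, "X", 1),)), 5)
        assert trace.values("X") == (0, 0, 1, 1, 1)

    def test_fold_equivalence_with_step(self):
        model = build_feedback("negative")
        initial = all_off(model, X=1)
        trace = simulate(model, initial, horizon=6)
        config = dict(initial)
        for k in range(6):
            assert trace.configs[k] == config
            config = step(model, config)

    def test_constant_on_attractor_state(self):
        model = build_feedback("double_positive")
        fixed = all_off(model, X=1, Y=1)
        trace = simulate(model, fixed, horizon=5)
        assert all(c == fixed for c in trace.configs)

    def test_independent_unscheduled_components_are_constant(self):
        model = build_ffl("i1")
        trace = simulate(model, all_off(model), InputSchedule(((2, "X", 1),)), 8)
        assert set(trace.values("S_X")) == {1}
        assert set(trace.values("S_Y")) == {1}

    def test_schedule_must_target_independent_components(self):
        model = build_ffl("c1")
        with pytest.raises(ScheduleError, match="regulated"):
            simulate(model, all_off(model), InputSchedule(((2, "Y", 1),)), 8)

    def test_schedule_time_must_be_inside_window(self):
        model = build_ffl("c1")
        with pytest.raises(ScheduleError, match="outside"):
            simulate(model, all_off(model), InputSchedule(((9, "X", 1),)), 8)

    def test_start_offset_relabels_instants(self):
        model = build_ffl("c1")
        trace = simulate(
            model, all_off(model), InputSchedule(((3, "X", 1),)), 8, start=1
        )
        assert trace.instants == range(1, 9)
        assert first_on_time(trace, "Y") == 4

    def test_duplicate_event_rejected(self):
        with pytest.raises(ScheduleError, match="duplicate"):
            InputSchedule(((2, "X", 1), (2, "X", 0)))


class TestAttractors:
    def test_double_positive_has_two_fixed_points_and_one_cycle(self):
        model = build_feedback("double_positive")
        attractors = enumerate_attractors(model, SIGNALS_ON)
        assert len(attractors) == 3
        kinds = sorted(a.kind for a in attractors)
        assert kinds == ["cycle", "fixed_point", "fixed_point"]
        fixed = {
            (a.states[0]["X"], a.states[0]["Y"])
            for a in attractors
            if a.kind == "fixed_point"
        }
        assert fixed == {(0, 0), (1, 1)}
        cycle = next(a for a in attractors if a.kind == "cycle")
        assert cycle.period == 2
        assert {(s["X"], s["Y"]) for s in cycle.states} == {(1, 0), (0, 1)}

    def test_negative_feedback_unique_period4_cycle(self):
        model = build_feedback("negative")
        attractors = enumerate_attractors(model, SIGNALS_ON)
        assert len(attractors) == 1
        assert attractors[0].kind == "cycle"
        assert attractors[0].period == 4
        assert attractors[0].basin_size == 4

    def test_negative_autoregulation_period2(self):
        model = build_autoregulation("negative")
        attractors = enumerate_attractors(model)
        assert len(attractors) == 1
        assert attractors[0].kind == "cycle" and attractors[0].period == 2

    def test_cycle_listed_from_lexicographically_smallest_state(self):
        model = build_feedback("negative")
        (cycle,) = enumerate_attractors(model, SIGNALS_ON)
        keys = [_state_key(model, s) for s in cycle.states]
        assert keys[0] == min(keys)
        # step order within the listing
        for a, b in zip(cycle.states, cycle.states[1:] + cycle.states[:1]):
            assert step(model, a) == b

    def test_basins_cover_the_enumerated_space(self):
        for name in MOTIF_BUILDERS:
            model = build_named(name)
            clamp = {n: 1 for n in model.independent_names() if n.startswith("S_")}
            attractors = enumerate_attractors(model, clamp)
            free = len(model.component_names) - len(clamp)
            assert sum(a.basin_size for a in attractors) == 2**free

    def test_agrees_with_simulation_from_every_initial_state(self):
        # oracle: simulate from every initial state until a revisit and
        # collect the periodic orbits reached; must equal the enumeration
        for name in MOTIF_BUILDERS:
            model = build_named(name)
            clamp = {n: 1 for n in model.independent_names() if n.startswith("S_")}
            names = model.component_names
            free = [n for n in names if n not in clamp]
            orbits = set()
            for bits in itertools.product((0, 1), repeat=len(free)):
                config = dict(zip(free, bits))
                config.update(clamp)
                seen = {}
                path = []
                key = _state_key(model, config)
                while key not in seen:
                    seen[key] = len(path)
                    path.append(key)
                    config = step(model, dict(zip(names, key)))
                    key = _state_key(model, config)
                cycle = tuple(path[seen[key]:])
                i = cycle.index(min(cycle))
                orbits.add(cycle[i:] + cycle[:i])
            enumerated = {
                tuple(_state_key(model, s) for s in a.states)
                for a in enumerate_attractors(model, clamp)
            }
            assert enumerated == orbits, name

    def test_state_space_cap(self):
        model = build_ffl("c1")
        with pytest.raises(StateSpaceTooLargeError):
            enumerate_attractors(model, max_states=4)

    def test_clamp_must_name_independent_component(self):
        model = build_ffl("c1")
        with pytest.raises(ValueError, match="regulated"):
            enumerate_attractors(model, {"Y": 1})


def make_trace(values, component="Z", start=0):
    return Trace(
        model_name="synthetic",
        components=(component,),
        configs=tuple({component: v} for v in values),
        start=start,
    )


class TestTraceAnalyses:
    def test_first_on_time_none_when_never_on(self):
        assert first_on_time(make_trace([0, 0, 0]), "Z") is None

    def test_first_on_unknown_component(self):
        with pytest.raises(KeyError, match="W"):
            first_on_time(make_trace([0, 1]), "W")

    def test_detect_pulses_run_length_scan(self):
        pulses = detect_pulses(make_trace([0, 1, 1, 0, 1, 0]), "Z")
        assert pulses == [Pulse(1, 2, False), Pulse(4, 1, False)]

    def test_detect_pulses_flags_boundary_runs(self):
        runs = detect_pulses(make_trace([1, 1, 0, 1, 1]), "Z")
        assert runs == [Pulse(0, 2, True), Pulse(3, 2, True)]

    def test_detect_pulses_empty_on_all_off(self):
        assert detect_pulses(make_trace([0, 0, 0]), "Z") == []

    def test_oscillation_period_negative_feedback(self):
        model = build_feedback("negative")
        for bits in itertools.product((0, 1), repeat=2):
            initial = {"X": bits[0], "Y": bits[1], **SIGNALS_ON}
            trace = simulate(model, initial, horizon=12)
            assert oscillation_period(trace) == 4

    def test_oscillation_period_fixed_point_is_one(self):
        model = build_feedback("double_positive")
        trace = simulate(model, {"X": 1, "Y": 1, **SIGNALS_ON}, horizon=6)
        assert oscillation_period(trace) == 1

    def test_oscillation_period_none_without_repeat(self):
        trace = make_trace([0, 1])
        assert oscillation_period(trace) is None

    def test_transient_is_removed_before_period_detection(self):
        model = build_ffl("c1")
        trace = simulate(model, all_off(model), InputSchedule(((2, "X", 1),)), 10)
        # settles to the all-on fixed point after the switching transient
        assert oscillation_period(trace) == 1


class TestBistability:
    def test_double_positive_joint_bistability(self):
        model = build_feedback("double_positive")
        pair = (
            {"X": 0, "Y": 0, **SIGNALS_ON},
            {"X": 1, "Y": 1, **SIGNALS_ON},
        )
        report = check_bistability(model, SIGNALS_ON, [pair])
        assert report.bistable
        assert {(s["X"], s["Y"]) for s in report.non_converging} == {(1, 0), (0, 1)}

    def test_double_negative_exclusive_bistability(self):
        model = build_feedback("double_negative")
        pair = (
            {"X": 1, "Y": 0, **SIGNALS_ON},
            {"X": 0, "Y": 1, **SIGNALS_ON},
        )
        report = check_bistability(model, SIGNALS_ON, [pair])
        assert report.bistable
        assert {(s["X"], s["Y"]) for s in report.non_converging} == {(0, 0), (1, 1)}

    def test_non_fixed_pair_is_reported(self):
        model = build_feedback("negative")
        pair = (
            {"X": 0, "Y": 0, **SIGNALS_ON},
            {"X": 1, "Y": 1, **SIGNALS_ON},
        )
        report = check_bistability(model, SIGNALS_ON, [pair])
        assert not report.bistable

    def test_empty_pair_list(self):
        model = build_feedback("double_positive")
        report = check_bistability(model, SIGNALS_ON, [])
        assert report.pairs == ()
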