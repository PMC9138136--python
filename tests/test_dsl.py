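"""Parser, validator and interpreter semantics of the protocol language."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioreact import (
    Command,
    Opcode,
    RecordingBus,
    format_script,
    parse_script,
    run,
    validate_script,
)
from bioreact.dsl import InterpreterState, step
from bioreact.errors import (
    MaxStepsExceededError,
    ScriptParseError,
    ScriptRuntimeError,
)
from reference_interpreter import evaluate
from script_gen import random_script_text

# ---------------------------------------------------------------------------
# parsing


@pytest.mark.parametrize(
    "text, opcode, value",
    [
        ("Vol 2", Opcode.VOL, 2.0),
        ("vol 2.5", Opcode.VOL, 2.5),          # case-insensitive
        ("Wait 06:00:00", Opcode.WAIT, 21600), # a 6-h refresh period
        ("Wait 00:00:09", Opcode.WAIT, 9),
        ("Loop 3", Opcode.LOOP, 3),
        ("Goto 2", Opcode.GOTO, 2),
        ("Dir B", Opcode.DIR, "B"),
        ("dir f", Opcode.DIR, "F"),
        ("Ch W1", Opcode.CH, "W1"),
        ("Stir A", Opcode.STIR, "A"),
        ("Start", Opcode.START, None),
        ("Msgbox media refreshed", Opcode.MSGBOX, "media refreshed"),
    ],
)
def test_parse_single_command(text, opcode, value):
    script = parse_script(text)
    assert len(script) == 1
    assert script.lines[0].command == Command(opcode, value)


def test_parse_empty_text_gives_empty_script():
    assert len(parse_script("")) == 0
    assert format_script(parse_script("")) == ""


def test_comments_and_blank_lines_are_skipped_and_numbering_is_logical():
    script = parse_script("# refresh protocol\n\nVol 2\n\n# drain\nDir B\n")
    assert [(l.number, l.command.opcode) for l in script.lines] == [
        (1, Opcode.VOL), (2, Opcode.DIR),
    ]
    assert script.lines[1].source_line == 6


@pytest.mark.parametrize(
    "text, field",
    [
        ("Dir X", "direction"),
        ("Vol abc", "volume"),
        ("Vol -1", "volume"),
        ("Wait 00:61:00", "duration"),
        ("Wait 1:2:3", "duration"),     # strict hh:mm:ss zero-padding
        ("Loop 0", "count"),
        ("Goto 0", "target"),
        ("Start now", "value"),
    ],
)
def test_malformed_values_name_line_and_field(text, field):
    with pytest.raises(ScriptParseError) as err:
        parse_script(text)
    assert err.value.line_no == 1
    assert err.value.field == field


def test_unknown_opcode_names_the_line():
    with pytest.raises(ScriptParseError) as err:
        parse_script("Vol 2\nFrobnicate 1")
    assert err.value.line_no == 2


# round-trip property: format(parse(t)) reparses to an equal script
_command_text = st.one_of(
    st.integers(1, 5).map(lambda n: f"Loop {n}"),
    st.floats(0.1, 10.0, allow_nan=False).map(lambda v: f"Vol {round(v, 2)}"),
    st.integers(1, 10).map(lambda n: f"Goto {n}"),
    st.tuples(st.integers(0, 99), st.integers(0, 59), st.integers(0, 59)).map(
        lambda t: f"Wait {t[0]:02d}:{t[1]:02d}:{t[2]:02d}"),
    st.sampled_from(["Dir F", "Dir B", "Ch A", "Ch W1", "Stir B", "Start",
                     "Msgbox hello world"]),
)


@settings(derandomize=True, max_examples=200)
@given(st.lists(_command_text, max_size=12))
def test_format_parse_round_trip(lines):
    script = parse_script("\n".join(lines))
    assert parse_script(format_script(script)) == script


# ---------------------------------------------------------------------------
# validation


def test_validate_dangling_goto():
    diags = validate_script(parse_script("Goto 5"))
    assert [d.severity for d in diags] == ["error"]
    assert "Goto target 5" in diags[0].message


def test_validate_clean_pump_sequence(config):
    script = parse_script("Vol 2\nDir B\nCh W1\nStart")
    assert validate_script(script, config) == []


def test_validate_vol_over_capacity(config):
    diags = validate_script(parse_script("Vol 12\nDir B\nCh W1\nStart"), config)
    assert len(diags) == 1 and diags[0].severity == "error"
    assert "Vol 12 exceeds capacity 10" in diags[0].message


def test_validate_start_without_registers():
    diags = validate_script(parse_script("Start"))
    assert diags[0].severity == "error"
    assert "Vol" in diags[0].message and "Ch" in diags[0].message


def test_validate_unknown_channel(config):
    diags = validate_script(parse_script("Ch NOPE"), config)
    assert any("unknown channel" in d.message for d in diags)
    # without a config the channel namespace is open
    assert validate_script(parse_script("Ch NOPE")) == []


def test_validate_warns_on_nested_loop():
    diags = validate_script(parse_script("Loop 2\nLoop 3\nStir A\nGoto 3"))
    assert [d.severity for d in diags] == ["warning"]


# ---------------------------------------------------------------------------
# execution semantics


def test_wait_advances_clock_only():
    trace = run(parse_script("Wait 00:10:00"), RecordingBus())
    assert trace.final_clock_s == 600.0
    assert len(trace.events) == 0


def test_loop_goto_repeats_block_n_times():
    # Loop 3 / Stir A / Goto 2 toggles the stirrer exactly 3 times: off->on->off->on
    trace = run(parse_script("Loop 3\nStir A\nGoto 2"), RecordingBus())
    stirs = [e for e in trace.events if e.event_type == "stir"]
    assert [e.detail for e in stirs] == ["on", "off", "on"]
    assert trace.final_state.stirrers["A"] is True


def test_goto_without_armed_loop_falls_through():
    trace = run(parse_script("Goto 1\nMsgbox done"), RecordingBus())
    assert [e.detail for e in trace.events] == ["done"]


def test_start_emits_pump_event_with_registers():
    bus = RecordingBus()
    trace = run(parse_script("Vol 2\nDir B\nCh W1\nStart"), bus)
    pump = [e for e in trace.events if e.event_type == "pump"]
    assert len(pump) == 1
    assert (pump[0].volume_ml, pump[0].direction, pump[0].channel) == (2.0, "B", "W1")
    # 2 mL at the default 2 mL/min takes one minute of simulated time
    assert trace.final_clock_s == 60.0
    assert ("pump", 2.0, "B", "W1", 2.0) in bus.calls


def test_start_without_channel_is_a_runtime_error():
    with pytest.raises(ScriptRuntimeError, match="no channel selected"):
        run(parse_script("Vol 2\nDir B\nStart"), RecordingBus())


def test_msgbox_never_blocks_and_is_logged():
    trace = run(parse_script("Msgbox done"), RecordingBus())
    assert len(trace.events) == 1
    assert trace.events[0].event_type == "message"
    assert trace.events[0].detail == "done"


def test_runaway_loop_hits_max_steps_guard():
    # Loop re-arms the counter every pass: an intentional infinite loop
    with pytest.raises(MaxStepsExceededError):
        run(parse_script("Loop 2\nGoto 1"), RecordingBus(), max_steps=500)


def test_empty_script_runs_to_empty_trace():
    trace = run(parse_script(""), RecordingBus())
    assert len(trace.events) == 0 and trace.final_clock_s == 0.0


def test_step_count_and_clock_are_monotone():
    script = parse_script("Loop 3\nStir A\nWait 00:00:01\nGoto 2\nMsgbox end")
    state = InterpreterState()
    bus = RecordingBus()
    clocks, steps = [0.0], [0]
    while state.pc < len(script.lines):
        state, _ = step(state, script, bus)
        clocks.append(state.clock_s)
        steps.append(state.step_count)
    assert clocks == sorted(clocks)
    assert steps == list(range(len(steps)))


def test_trace_timestamps_non_decreasing(rng):
    for _ in range(50):
        script = parse_script(random_script_text(rng))
        try:
            trace = run(script, RecordingBus(), max_steps=1000)
        except ScriptRuntimeError:
            continue
        stamps = [e.elapsed_s for e in trace.events]
        assert stamps == sorted(stamps)


# ---------------------------------------------------------------------------
# oracle equivalence (small-n version of the full acceptance check)


def _run_to_comparable(script):
    bus = RecordingBus()
    try:
        trace = run(script, bus, max_steps=200)
    except MaxStepsExceededError as exc:
        return None, ("max-steps", exc.line_no)
    except ScriptRuntimeError as exc:
        return None, ("runtime-error", exc.line_no, str(exc).split(": ", 1)[1])
    events = [
        (e.elapsed_s, e.event_type, e.channel, e.volume_ml, e.direction, e.detail)
        for e in trace.events
    ]
    return events, ("ok", trace.final_clock_s)


def test_interpreter_matches_brute_force_oracle(rng):
    for _ in range(200):
        script = parse_script(random_script_text(rng))
        ref_events, ref_outcome = evaluate(script, max_steps=200)
        got_events, got_outcome = _run_to_comparable(script)
        assert got_outcome == ref_outcome
        if got_outcome[0] == "ok":
            assert got_events == ref_events


# ---------------------------------------------------------------------------
# trace CSV round trip


def test_event_trace_csv_round_trip(tmp_path):
    from bioreact import EventTrace

    trace = run(parse_script("Vol 2\nDir B\nCh W1\nStart\nMsgbox ok"), RecordingBus())
    path = tmp_path / "events.csv"
    trace.to_csv(path)
    back = EventTrace.from_csv(path)
    assert [
        (e.elapsed_s, e.event_type, e.channel, e.volume_ml, e.direction, e.detail)
        for e in back.events
    ] == [
        (e.elapsed_s, e.event_type, e.channel, e.volume_ml, e.direction, e.detail)
        for e in trace.events
    ]
    header = path.read_text().splitlines()[0]
    assert header == "elapsed_s,event_type,channel,volume_ml,direction,detail"
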