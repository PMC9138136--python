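"""The bioreactor protocol scripting language: parser, validator, interpreter.

Protocols are plain-text scripts, one command per line, drawn from a
9-command set:

=========  =============================  ==========================================
Command    Value                          Meaning
=========  =============================  ==========================================
Loop       number                         Arm the repeat counter (see below)
Vol        number                         Set syringe volume to fill/drain (mL)
Goto       number                         Jump to a script line number
Wait       hh:mm:ss                       Delay
Dir        F or B                         Pump direction (Forward = dispense,
                                          Backward = withdraw)
Ch         channel id                     Select a selector channel
Stir       channel id                     Toggle that well's stirrer on/off
Start                                     Run the syringe pump with the current
                                          Vol/Dir/Ch registers
Msgbox     text                           Log a message (never blocks)
=========  =============================  ==========================================

Loop/Goto convention
--------------------
``Loop n`` arms a single repeat counter with ``n - 1`` remaining passes; the
next ``Goto`` executed consumes it: while the counter is positive it
decrements and jumps, and when it reaches zero it falls through to the next
line.  A block bracketed as ``Loop n ... Goto <block start>`` therefore
executes exactly ``n`` times.  There is a single loop register, so loops do
not nest; the validator warns if a second ``Loop`` appears before a ``Goto``
can drain the first.

Lines are numbered 1..n over the command lines in file order; ``Goto``
targets refer to these logical numbers.  Blank lines and lines starting with
``#`` are ignored (and stripped by the formatter).  Opcodes are
case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .errors import (
    MaxStepsExceededError,
    ScriptParseError,
    ScriptRuntimeError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .hardware import DeviceBus

DEFAULT_MAX_STEPS = 100_000

TRACE_COLUMNS = ["elapsed_s", "event_type", "channel", "volume_ml", "direction", "detail"]


class Opcode(Enum):
    LOOP = "Loop"
    VOL = "Vol"
    GOTO = "Goto"
    WAIT = "Wait"
    DIR = "Dir"
    CH = "Ch"
    STIR = "Stir"
    START = "Start"
    MSGBOX = "Msgbox"


_OPCODES = {op.value.lower(): op for op in Opcode}

_TIME_RE = re.compile(r"^(\d+):([0-5]\d):([0-5]\d)$")


@dataclass(frozen=True)
class Command:
    """One parsed command: an opcode plus its typed payload.

    Payload types: ``int`` repeat count for LOOP, ``float`` mL for VOL,
    ``int`` line number for GOTO, ``int`` seconds for WAIT, ``'F'``/``'B'``
    for DIR, channel-id ``str`` for CH/STIR, message ``str`` for MSGBOX,
    ``None`` for START.
    """

    opcode: Opcode
    value: object = None


@dataclass(frozen=True)
class ScriptLine:
    number: int          # logical line number (Goto target space)
    command: Command
    source_line: int = 0  # 1-based line in the source text (for error messages)


@dataclass(frozen=True, eq=False)
class Script:
    """An ordered, numbered protocol script.

    Equality compares the logical lines only, so a formatted round trip
    (``parse(format(script))``) is equal to the original even though the raw
    source text differs.
    """

    lines: tuple[ScriptLine, ...]
    source_text: str = ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Script):
            return NotImplemented
        return [(l.number, l.command) for l in self.lines] == [
            (l.number, l.command) for l in other.lines
        ]

    def __hash__(self) -> int:
        return hash(tuple((l.number, l.command) for l in self.lines))

    def __len__(self) -> int:
        return len(self.lines)

    def index_of(self, line_number: int) -> int | None:
        for i, line in enumerate(self.lines):
            if line.number == line_number:
                return i
        return None


def _parse_duration(raw: str) -> int:
    m = _TIME_RE.match(raw)
    if not m:
        raise ValueError(f"{raw!r} is not hh:mm:ss with mm, ss in [0, 59]")
    h, mnt, s = (int(g) for g in m.groups())
    return h * 3600 + mnt * 60 + s


def _format_duration(seconds: int) -> str:
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def _parse_command(opcode_raw: str, rest: str, source_line: int) -> Command:
    op = _OPCODES.get(opcode_raw.lower())
    if op is None:
        raise ScriptParseError(f"unknown opcode {opcode_raw!r}", line_no=source_line)

    def bad(field_name: str, msg: str) -> ScriptParseError:
        return ScriptParseError(msg, line_no=source_line, field=field_name)

    if op is Opcode.LOOP:
        try:
            n = int(rest)
        except ValueError:
            raise bad("count", f"Loop count must be an integer, got {rest!r}") from None
        if n < 1:
            raise bad("count", f"Loop count must be >= 1, got {n}")
        return Command(op, n)
    if op is Opcode.VOL:
        try:
            v = float(rest)
        except ValueError:
            raise bad("volume", f"Vol value must be numeric, got {rest!r}") from None
        if v <= 0:
            raise bad("volume", f"Vol value must be > 0 mL, got {v}")
        return Command(op, v)
    if op is Opcode.GOTO:
        try:
            target = int(rest)
        except ValueError:
            raise bad("target", f"Goto target must be an integer, got {rest!r}") from None
        if target < 1:
            raise bad("target", f"Goto target must be a positive line number, got {target}")
        return Command(op, target)
    if op is Opcode.WAIT:
        try:
            return Command(op, _parse_duration(rest))
        except ValueError as exc:
            raise bad("duration", str(exc)) from None
    if op is Opcode.DIR:
        d = rest.strip().upper()
        if d not in ("F", "B"):
            raise bad("direction", f"Dir must be F or B, got {rest!r}")
        return Command(op, d)
    if op in (Opcode.CH, Opcode.STIR):
        token = rest.strip()
        if not token or len(token.split()) != 1:
            raise bad("channel", f"{op.value} needs a single channel id, got {rest!r}")
        return Command(op, token)
    if op is Opcode.START:
        if rest.strip():
            raise bad("value", f"Start takes no value, got {rest!r}")
        return Command(op, None)
    # MSGBOX: free text, may be empty
    return Command(op, rest.strip())


def parse_script(text: str) -> Script:
    """Parse protocol-script source into a :class:`Script`.

    Blank lines and ``#`` comment lines are skipped; surviving command lines
    are numbered from 1 in file order.  Raises :class:`ScriptParseError`
    naming the source line (and field, for a malformed value).
    """
    lines: list[ScriptLine] = []
    logical = 0
    for source_line, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(None, 1)
        opcode_raw = parts[0]
        rest = parts[1] if len(parts) > 1 else ""
        logical += 1
        cmd = _parse_command(opcode_raw, rest, source_line)
        lines.append(ScriptLine(number=logical, command=cmd, source_line=source_line))
    return Script(lines=tuple(lines), source_text=text)


def load_script(path: str | Path) -> Script:
    return parse_script(Path(path).read_text())


def _format_value(cmd: Command) -> str:
    op, v = cmd.opcode, cmd.value
    if op is Opcode.START:
        return ""
    if op is Opcode.VOL:
        return f"{v:g}"
    if op is Opcode.WAIT:
        return _format_duration(v)
    return str(v)


def format_script(script: Script) -> str:
    """Canonical text form: one command per line, comments stripped."""
    out = []
    for line in script.lines:
        value = _format_value(line.command)
        out.append(f"{line.command.opcode.value} {value}".rstrip())
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Diagnostic:
    line: int
    severity: str  # "error" | "warning"
    message: str


def validate_script(script: Script, config=None) -> list[Diagnostic]:
    """Static checks; returns diagnostics (empty list = clean).

    Errors: dangling Goto targets; Vol above the syringe capacity; a Start
    with no Vol, Dir and Ch earlier in the script; unknown Ch/Stir channel
    ids.  Warnings: a second Loop armed before a Goto can drain the first
    (single loop register).

    ``config`` is a :class:`~bioreact.config.RunConfig` (or anything with
    ``pump.capacity_ml`` and a ``channels`` container); with ``None``, the
    default 10-mL capacity is assumed and channel ids are unchecked.
    """
    capacity = config.pump.capacity_ml if config is not None else 10.0
    channels = getattr(config, "channels", None)
    diags: list[Diagnostic] = []
    numbers = {line.number for line in script.lines}
    seen = {Opcode.VOL: False, Opcode.DIR: False, Opcode.CH: False}
    loop_armed = False
    for line in script.lines:
        cmd = line.command
        op = cmd.opcode
        if op is Opcode.GOTO:
            if cmd.value not in numbers:
                diags.append(Diagnostic(line.number, "error",
                                        f"unresolved Goto target {cmd.value}"))
            loop_armed = False
        elif op is Opcode.LOOP:
            if loop_armed:
                diags.append(Diagnostic(
                    line.number, "warning",
                    "second Loop armed before a Goto drained the first "
                    "(single loop register; loops do not nest)"))
            loop_armed = True
        elif op is Opcode.VOL:
            if cmd.value > capacity:
                diags.append(Diagnostic(line.number, "error",
                                        f"Vol {cmd.value:g} exceeds capacity {capacity:g}"))
            seen[op] = True
        elif op in (Opcode.DIR,):
            seen[op] = True
        elif op in (Opcode.CH, Opcode.STIR):
            if channels is not None and cmd.value not in channels:
                diags.append(Diagnostic(line.number, "error",
                                        f"unknown channel {cmd.value!r}"))
            if op is Opcode.CH:
                seen[op] = True
        elif op is Opcode.START:
            missing = [o.value for o in (Opcode.VOL, Opcode.DIR, Opcode.CH) if not seen[o]]
            if missing:
                diags.append(Diagnostic(
                    line.number, "error",
                    f"Start with no prior {'/'.join(missing)} in the script"))
    return diags


# ---------------------------------------------------------------------------
# execution


@dataclass(frozen=True)
class Event:
    """One time-stamped device action or message."""

    elapsed_s: float
    event_type: str  # "channel" | "stir" | "pump" | "message"
    channel: str | None = None
    volume_ml: float | None = None
    direction: str | None = None
    detail: str = ""


@dataclass
class InterpreterState:
    """Execution state of a running script."""

    pc: int = 0                      # index into script.lines
    pending_volume_ml: float = 0.0
    direction: str | None = None
    active_channel: str | None = None
    stirrers: dict[str, bool] = field(default_factory=dict)
    loop_counter: int = 0
    loop_body_start: int | None = None  # logical line after the last Loop
    clock_s: float = 0.0
    step_count: int = 0

    def copy(self) -> "InterpreterState":
        return replace(self, stirrers=dict(self.stirrers))


def step(
    state: InterpreterState,
    script: Script,
    bus: "DeviceBus",
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[InterpreterState, list[Event]]:
    """Execute exactly one command; return the successor state and any events.

    The simulated clock advances only on Wait (by the stated delay) and
    Start (by the pump-run duration reported by the bus); register commands
    are instantaneous.
    """
    if not 0 <= state.pc < len(script.lines):
        raise ScriptRuntimeError(f"program counter {state.pc} outside script")
    line = script.lines[state.pc]
    cmd = line.command
    new = state.copy()
    new.step_count += 1
    if new.step_count > max_steps:
        raise MaxStepsExceededError(
            f"exceeded max-steps guard ({max_steps}); likely a runaway Loop/Goto",
            line_no=line.number,
        )
    events: list[Event] = []
    op = cmd.opcode

    if op is Opcode.LOOP:
        new.loop_counter = cmd.value - 1
        new.loop_body_start = line.number + 1
        new.pc += 1
    elif op is Opcode.GOTO:
        if new.loop_counter > 0:
            new.loop_counter -= 1
            target_index = script.index_of(cmd.value)
            if target_index is None:
                raise ScriptRuntimeError(
                    f"unresolved Goto target {cmd.value}", line_no=line.number
                )
            new.pc = target_index
        else:
            new.pc += 1
    elif op is Opcode.WAIT:
        bus.elapse(cmd.value)
        new.clock_s = round(new.clock_s + cmd.value, 6)
        new.pc += 1
    elif op is Opcode.VOL:
        new.pending_volume_ml = cmd.value
        new.pc += 1
    elif op is Opcode.DIR:
        new.direction = cmd.value
        new.pc += 1
    elif op is Opcode.CH:
        new.active_channel = cmd.value
        bus.set_channel(cmd.value)
        events.append(Event(new.clock_s, "channel", channel=cmd.value))
        new.pc += 1
    elif op is Opcode.STIR:
        on = not new.stirrers.get(cmd.value, False)  # all stirrers start off
        new.stirrers[cmd.value] = on
        bus.set_stirrer(cmd.value, on)
        events.append(Event(new.clock_s, "stir", channel=cmd.value,
                            detail="on" if on else "off"))
        new.pc += 1
    elif op is Opcode.START:
        if new.active_channel is None:
            raise ScriptRuntimeError("no channel selected", line_no=line.number)
        if new.direction is None:
            raise ScriptRuntimeError("no pump direction set", line_no=line.number)
        if new.pending_volume_ml <= 0:
            raise ScriptRuntimeError("no pump volume set", line_no=line.number)
        duration = bus.run_pump(new.pending_volume_ml, new.direction, new.active_channel)
        new.clock_s = round(new.clock_s + duration, 6)
        events.append(Event(
            new.clock_s, "pump",
            channel=new.active_channel,
            volume_ml=new.pending_volume_ml,
            direction=new.direction,
            detail=f"duration_s={duration:g}",
        ))
        new.pc += 1
    elif op is Opcode.MSGBOX:
        events.append(Event(new.clock_s, "message", detail=cmd.value))
        new.pc += 1
    else:  # pragma: no cover - exhaustive
        raise ScriptRuntimeError(f"unhandled opcode {op}", line_no=line.number)
    return new, events


@dataclass(frozen=True)
class EventTrace:
    """Time-stamped record of every device event and message in a run."""

    events: tuple[Event, ...]
    final_clock_s: float = 0.0
    final_state: InterpreterState | None = None

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.elapsed_s, e.event_type, e.channel, e.volume_ml, e.direction, e.detail)
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=TRACE_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTrace":
        df = pd.read_csv(path)
        events = []
        for row in df.itertuples(index=False):
            events.append(Event(
                elapsed_s=float(row.elapsed_s),
                event_type=str(row.event_type),
                channel=None if pd.isna(row.channel) else str(row.channel),
                volume_ml=None if pd.isna(row.volume_ml) else float(row.volume_ml),
                direction=None if pd.isna(row.direction) else str(row.direction),
                detail="" if pd.isna(row.detail) else str(row.detail),
            ))
        final = events[-1].elapsed_s if events else 0.0
        return cls(events=tuple(events), final_clock_s=final)


def run(
    script: Script,
    bus: "DeviceBus",
    max_steps: int = DEFAULT_MAX_STEPS,
    initial_state: InterpreterState | None = None,
) -> EventTrace:
    """Execute a script to completion and return the full event trace.

    Iterates :func:`step` until the program counter passes the last line.
    Raises :class:`MaxStepsExceededError` if the guard trips (so no script
    can hang), and propagates runtime errors with the offending line number.
    """
    state = initial_state or InterpreterState()
    events: list[Event] = []
    while state.pc < len(script.lines):
        state, new_events = step(state, script, bus, max_steps=max_steps)
        events.extend(new_events)
    return EventTrace(
        events=tuple(events), final_clock_s=state.clock_s, final_state=state
    )
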