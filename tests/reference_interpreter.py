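"""Independent brute-force reference evaluator for protocol scripts.

Deliberately written as a plain line-by-line walk with an explicit jump
table and no shared execution code with ``bioreact.dsl``: it serves as the
oracle the real interpreter's event traces are compared against.  Events are
plain tuples ``(elapsed_s, event_type, channel, volume_ml, direction,
detail)``; timestamps follow the same microsecond-rounding convention as the
interpreter.  The outcome is ``("ok", final_clock)``, ``("max-steps",
line)`` or ``("runtime-error", line, message)``.
"""

from __future__ import annotations

from bioreact.dsl import Opcode, Script


def evaluate(
    script: Script,
    rate_ml_min: float = 2.0,
    max_steps: int = 100_000,
) -> tuple[list[tuple], tuple]:
    jump_table = {line.number: idx for idx, line in enumerate(script.lines)}
    events: list[tuple] = []
    pc = 0
    clock = 0.0
    vol = 0.0
    direction = None
    channel = None
    stirrers: dict[str, bool] = {}
    counter = 0
    steps = 0

    while pc < len(script.lines):
        line = script.lines[pc]
        steps += 1
        if steps > max_steps:
            return events, ("max-steps", line.number)
        op = line.command.opcode
        val = line.command.value
        if op is Opcode.LOOP:
            counter = val - 1
            pc += 1
        elif op is Opcode.GOTO:
            if counter > 0:
                counter -= 1
                pc = jump_table[val]
            else:
                pc += 1
        elif op is Opcode.WAIT:
            clock = round(clock + val, 6)
            pc += 1
        elif op is Opcode.VOL:
            vol = val
            pc += 1
        elif op is Opcode.DIR:
            direction = val
            pc += 1
        elif op is Opcode.CH:
            channel = val
            events.append((clock, "channel", val, None, None, ""))
            pc += 1
        elif op is Opcode.STIR:
            state = not stirrers.get(val, False)
            stirrers[val] = state
            events.append((clock, "stir", val, None, None, "on" if state else "off"))
            pc += 1
        elif op is Opcode.START:
            if channel is None:
                return events, ("runtime-error", line.number, "no channel selected")
            if direction is None:
                return events, ("runtime-error", line.number, "no pump direction set")
            if vol <= 0:
                return events, ("runtime-error", line.number, "no pump volume set")
            duration = vol / rate_ml_min * 60.0
            clock = round(clock + duration, 6)
            events.append((clock, "pump", channel, vol, direction, f"duration_s={duration:g}"))
            pc += 1
        elif op is Opcode.MSGBOX:
            events.append((clock, "message", None, None, None, val))
            pc += 1
        else:  # pragma: no cover
            raise AssertionError(f"unknown opcode {op}")
    return events, ("ok", clock)
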