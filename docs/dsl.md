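# Protocol scripting language reference

Protocol scripts are plain UTF-8 text, one command per line, in the form
`<opcode> <value>` with whitespace separation. Opcodes are
case-insensitive. Blank lines and lines whose first non-blank character is
`#` are comments and are ignored (the canonical formatter strips them).
Command lines are numbered 1..n in file order — these logical numbers are
what `Goto` targets refer to, so interleaved comments do not shift jump
targets.

## Commands

| Command  | Value                      | Meaning |
|----------|----------------------------|---------|
| `Loop`   | integer ≥ 1                | Arm the repeat counter (see below). |
| `Vol`    | number > 0                 | Set the syringe volume to fill or drain, in mL. Must not exceed the configured syringe capacity (default 10 mL). |
| `Goto`   | line number                | Jump to a script line (consumes the repeat counter). |
| `Wait`   | `hh:mm:ss` (strict; mm, ss in 00–59) | Delay. In simulation the clock advances instantly and the culture model integrates across the delay. |
| `Dir`    | `F` or `B`                 | Pump direction: `F`orward dispenses from the syringe, `B`ackward withdraws into it. |
| `Ch`     | channel id                 | Select a selector channel (a well, `FRESH`, or `WASTE` in the default table). Selection is exclusive. |
| `Stir`   | channel id                 | Toggle that well's stirrer. All stirrers start off. |
| `Start`  | —                          | Run the pump with the current `Vol`/`Dir`/`Ch` registers. Duration = volume / flow rate. |
| `Msgbox` | free text                  | Log a message. Never blocks, so unattended protocols keep running. |

## The Loop/Goto convention

There is a single repeat register. `Loop n` arms it with `n − 1` remaining
passes. The next `Goto` executed consumes it: while the register is
positive it decrements and jumps to its target; at zero it falls through to
the following line. A block bracketed as

```
Loop 3
Stir A
Goto 2
```

therefore executes `Stir A` exactly three times. A `Goto` with the register
at zero never jumps, and a `Goto` that jumps back *onto* the `Loop` line
re-arms the register each pass and loops forever — the interpreter's
max-steps guard (default 100 000 executed instructions) turns any such
runaway into an error instead of a hang. Loops do not nest; the validator
warns when a second `Loop` is armed before a `Goto` can drain the first.

## Static validation

`bioreact validate script.bps` (or `bioreact.validate_script`) reports:

* **errors** — unresolved `Goto` targets; `Vol` above the syringe capacity;
  a `Start` with no `Vol`, `Dir` and `Ch` earlier in the script; unknown
  channel ids (when a config with a channel table is supplied);
* **warnings** — a second `Loop` before the first can drain.

Validation is static: a `Goto` can still skip the `Ch` belonging to a
`Start` at run time, which raises a runtime error naming the line.

## Event trace

Execution produces a time-stamped event trace, exported as CSV with columns
`elapsed_s,event_type,channel,volume_ml,direction,detail`. Event types are
`channel` (selector switched), `stir` (toggle, with `on`/`off` detail),
`pump` (one pump run with volume, direction, channel and duration) and
`message`. Register updates (`Vol`, `Dir`) and `Wait`/`Loop`/`Goto` emit no
events; timestamps are non-decreasing throughout.
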