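"""Random protocol-script generator for interpreter equivalence testing.

Generates short scripts (default <= 10 commands) whose static structure is
valid: Loop counts <= 3, Waits <= 10 s, Goto targets inside the script, and
every Start preceded in line order by Vol, Dir and Ch.  Runtime errors (a
jump that skips the Ch before a Start) are still possible and are part of
the behaviour under comparison.
"""

from __future__ import annotations

import numpy as np

CHANNELS = ["A", "B", "C"]


def random_script_text(
    rng: np.random.Generator,
    max_lines: int = 10,
    max_loop: int = 3,
    max_wait_s: int = 10,
) -> str:
    n = int(rng.integers(1, max_lines + 1))
    lines: list[str] = []
    seen = {"Vol": False, "Dir": False, "Ch": False}
    for i in range(n):
        ops = ["Loop", "Vol", "Wait", "Dir", "Ch", "Stir", "Msgbox"]
        if i > 0:
            ops.append("Goto")
        if all(seen.values()):
            ops += ["Start", "Start"]  # weight pump runs up once legal
        op = ops[rng.integers(0, len(ops))]
        if op == "Loop":
            lines.append(f"Loop {rng.integers(1, max_loop + 1)}")
        elif op == "Vol":
            lines.append(f"Vol {round(float(rng.uniform(0.5, 9.5)), 1)}")
            seen["Vol"] = True
        elif op == "Wait":
            lines.append(f"Wait 00:00:{rng.integers(0, max_wait_s + 1):02d}")
        elif op == "Dir":
            lines.append(f"Dir {'F' if rng.random() < 0.5 else 'B'}")
            seen["Dir"] = True
        elif op == "Ch":
            lines.append(f"Ch {CHANNELS[rng.integers(0, len(CHANNELS))]}")
            seen["Ch"] = True
        elif op == "Stir":
            lines.append(f"Stir {CHANNELS[rng.integers(0, len(CHANNELS))]}")
        elif op == "Goto":
            lines.append(f"Goto {rng.integers(1, n + 1)}")
        elif op == "Msgbox":
            lines.append(f"Msgbox step {i + 1}")
        else:
            lines.append("Start")
    return "\n".join(lines) + "\n"
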