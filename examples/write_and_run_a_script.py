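"""Write a protocol script by hand and execute it on the simulated rig.

Demonstrates the command language directly: drain 2 mL from well W1, push
it to waste past the pH sensor, draw fresh media, refill, stir, and wait.
"""

from bioreact import RunConfig, parse_script, validate_script
from bioreact.controller import run_script

SOURCE = """\
# one manual media exchange on well W1, repeated twice
Loop 2
Ch W1
Dir B
Vol 2
Start
Ch WASTE
Dir F
Start
Ch FRESH
Dir B
Start
Ch W1
Dir F
Start
Stir W1
Wait 01:00:00
Stir W1
Goto 2
Msgbox exchange done
"""

config = RunConfig.default(n_wells=1, seed=0)
script = parse_script(SOURCE)
print(f"parsed {len(script)} commands; diagnostics: {validate_script(script, config)}")

report = run_script(script, config, seed=0)
print(f"executed -> {report.summary['n_events']} events, "
      f"{report.summary['n_readings']} pH readings, "
      f"final clock {report.trace.final_clock_s / 3600:.2f} h")
for reading in report.sensor_log:
    print(f"  t = {reading.elapsed_s / 60:5.1f} min  well {reading.channel}  "
          f"green {reading.green_intensity:6.1f}  pH {reading.ph_estimate:.3f}")
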