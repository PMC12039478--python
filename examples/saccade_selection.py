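"""Saccade-target selection on a collicular grid via a spanning code.

A 20 x 20 build-up-layer grid receives external drive at one or two
target coordinates and tonic inhibition from 40 basal ganglia output
neurons, each spanning a full row or column.  Pausing two neurons selects
one coordinate; boosting another suppresses an unwanted competitor.
"""

from bgbottleneck import run_scenario, selectable_coordinates, spanning_code_capacity

for name in ("tonic", "pause", "competing", "competing_corrected"):
    report = run_scenario(name, target=(12, 7), competitor=(4, 7))
    locs = ", ".join(map(str, report.hill_locations)) or "none"
    print(f"{name:20s} -> {report.n_hills} hill(s) at {locs} "
          f"(peak activity {report.peak_activity:.2f})")

print("\ntonic: uniform inhibition suppresses the target drive entirely;")
print("pause: dropping the row-12 and column-7 neurons selects (12, 7);")
print("competing: a second target on column 7 leaks through the paused column;")
print("corrected: raising the row-4 neuron above tonic silences the competitor.")

n = selectable_coordinates(side=20, drive=1.5, tonic=1.0)
print(f"\nindividually selectable coordinates on the 20x20 grid: {n} "
      f"(= spanning capacity {spanning_code_capacity(40, 1.0)} for 40 neurons)")
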