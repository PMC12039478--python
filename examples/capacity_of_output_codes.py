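"""Coding capacity of a small inhibitory output population.

Compares three readings of what b tonically active output neurons can
signal: classic disinhibition (each neuron on/off), a three-state code
(below / at / above tonic rate), and the row/column spanning code for a
2-D target map.
"""

from bgbottleneck import (count_output_states, spanning_code_capacity,
                          topographic_capacity)

b = 100
binary = count_output_states(b, 2)
triple = count_output_states(b, 3)
print(f"{b} output neurons, on/off disinhibition: 2^{b} = {binary:.3e} states")
print(f"{b} output neurons, three-state code:     3^{b} = {triple}")
print(f"  exceeds 5e47: {triple > 5 * 10 ** 47}")

print("\nControllable 2-D coordinates, topographic vs spanning code:")
for neurons in (10, 20, 40, 50):
    print(f"  b={neurons:3d}:  topographic {topographic_capacity(neurons):4d}"
          f"   spanning {spanning_code_capacity(neurons, 1.0):5d}")

print("\nThe spanning code scales quadratically (b/2 * b/2 coordinates),")
print("so 40 neurons already control a 20 x 20 collicular grid (400 sites),")
print("where point-to-point wiring would control only 40.")
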