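"""Parallel-plate compression of a 3D culture: Young's modulus estimation.

Simulates the five-cycle protocol (25% engineering strain, 15/2/15/2 s
phases), segments the cycles, keeps the stabilised fifth compression phase,
and inverts the two-plate Hertz sphere model within the 10-20% strain linear
window, averaging the horizontal- and vertical-radius estimates.
"""

from fibromech import SynthProtocol, segment_cycles, synth_compression_test, young_modulus_sphere
from fibromech.compression import phase_durations, stabilisation_drift

test = synth_compression_test(
    5.0, r_h_um=500.0, r_v_um=450.0, protocol=SynthProtocol(seed=1), force_noise_rel=0.02
)
cycles = segment_cycles(test)
print(f"cycles found        : {len(cycles)} (protocol: {test.protocol.n_cycles})")
print(f"cycle-5 phases (s)  : {phase_durations(test, cycles[4])}")
print(f"preconditioning drift (peak force, cycle 4 -> 5): {stabilisation_drift(test):.4f}")

result = young_modulus_sphere(test)
print(f"E horizontal radius : {result.e_horizontal_kpa:.3f} kPa")
print(f"E vertical radius   : {result.e_vertical_kpa:.3f} kPa")
print(f"Young's modulus E   : {result.e_kpa:.3f} kPa (generator truth: 5 kPa; nu = 0.5)")
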