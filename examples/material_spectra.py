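"""Evaluate the packaged Debye material library over the measurement band.

Prints the real permittivity and equivalent conductivity of each library
material at the seven measurement frequencies (300-1500 MHz).  The 300 MHz
column is the one used to match the published reference values; strongly
relaxing liquids (ethanol, methanol) lose permittivity toward 1.5 GHz while
the dispersion-free solids/phantoms stay flat.
"""

from oecp import FrequencyGrid, evaluate_debye, load_material_library

grid = FrequencyGrid.default()
library = load_material_library()

header = "material".ljust(22) + "".join(f"{f/1e6:>9.0f}M" for f in grid)
print("Real permittivity eps'(f)")
print(header)
for name, mat in library.items():
    row = "".join(f"{evaluate_debye(mat, f).eps_real:>10.2f}" for f in grid)
    print(name.ljust(22) + row)

print("\nEquivalent conductivity sigma(f) [S/m]")
print(header)
for name, mat in library.items():
    row = "".join(f"{evaluate_debye(mat, f).sigma:>10.3f}" for f in grid)
    print(name.ljust(22) + row)
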