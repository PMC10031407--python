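"""Simulate spanwise strain in a flapping gradient-stiffness wing.

Builds the hawkmoth-scale plate wing with a log-gradient Young's modulus,
flaps it at 25 Hz (with a 50 Hz harmonic) and prints the stiffness-field
identities and strain magnitudes of the steady wingbeat.
"""

import numpy as np

from wingsense import (
    Kinematics, WingSpec, build_stiffness_field, eigenfrequency,
    simulate_strain,
)

spec = WingSpec(gradient="gradient", E_mean=3e9, zeta=2.0)

field = build_stiffness_field(spec)
print(f"stiffness range:  log10(E_max / E_min) = {field.log10_range:.3f} "
      "(the gradient spans two orders of magnitude)")
print(f"mean modulus:     {field.E.mean() / 1e9:.3f} GPa "
      "(normalised to the nominal 3 GPa)")

omega_n, _ = eigenfrequency(spec)
print(f"first eigenmode:  {omega_n / (2 * np.pi):.1f} Hz "
      "(sets the damping coefficient c = 2 zeta m omega_n)")

strain = simulate_strain(spec, Kinematics(rotation_axis="none"))
peak = np.abs(strain.window).max()
print(f"steady wingbeat:  reached after {strain.provenance['cycles_run']} cycles "
      f"(cycle-to-cycle change {strain.periodicity_error:.2%})")
print(f"peak |strain|:    {peak:.2e} "
      "(dimensionless spanwise surface strain; largest near the wing base)")
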