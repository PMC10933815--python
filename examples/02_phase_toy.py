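"""Two-voxel phase toy: amplitude falls as |cos(theta/2)| with dephasing.

Two voxels carry the same sinusoid with a phase offset theta.  With equal
positive map weights, the network timeseries is their average, whose SD is
proportional to |cos(theta/2)|: identical voxel amplitudes, but the network
amplitude collapses to zero as the voxels move into antiphase.  This is the
essence of why network amplitude measures synchrony, not signal size.
"""

import numpy as np

from rsnamp.decompose import network_amplitude, spatial_regress
from rsnamp.synthcohort import phase_toy

print(f"{'theta/pi':>9} {'amplitude':>10} {'|cos(theta/2)| x a(0)':>22}")
a0 = None
for frac in np.linspace(0, 1, 9):
    theta = frac * np.pi
    run, maps = phase_toy(theta, n_timepoints=2000, n_periods=10)
    a = network_amplitude(spatial_regress(run, maps))[0]
    a0 = a if a0 is None else a0
    print(f"{frac:9.3f} {a:10.6f} {a0 * abs(np.cos(theta / 2)):22.6f}")

print("\nThe measured amplitude matches the closed form at every offset; "
      "the voxel SDs never change.")
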