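"""Interfere a vortex beam with an expanded reference Gaussian.

On-axis interference of an LG_0^5 beam produces a 5-armed spiral whose
arm count equals the topological charge; tilting the reference (off-axis)
produces forked straight fringes with l extra fringe terminations.
"""

import numpy as np

from vortexmc import BeamSpec, FieldMap, PixelGrid, interferogram, wrap_phase

beam = BeamSpec(5, 0, 0.8, 633e-6)
grid = PixelGrid.centered(256, 0.02)
fm = FieldMap.from_beam(beam, grid)

# on-axis: spiral fringes
ig_on = interferogram(fm, beam, tilt=0.0, reference_amplitude=0.3)
theta = np.linspace(-np.pi, np.pi, 1440, endpoint=False)
r = beam.waist * np.sqrt(5 / 2)
iy, ix = grid.index_of(r * np.cos(theta), r * np.sin(theta))
ring = ig_on[iy, ix] - ig_on[iy, ix].mean()
arms = np.argmax(np.abs(np.fft.rfft(ring))[1:]) + 1
print(f"on-axis interferogram: {arms} spiral arms around the ring "
      f"(= |l| of the LG_0^{beam.topological_charge} beam)")

# off-axis: straight carrier fringes of period lambda/sin(tilt)
tilt = 0.01
ig_off = interferogram(fm, beam, tilt=tilt, reference_amplitude=0.3)
row = ig_off[grid.ny // 2] - ig_off[grid.ny // 2].mean()
freq = np.fft.rfftfreq(grid.nx, d=grid.pitch)
period = 1 / freq[np.argmax(np.abs(np.fft.rfft(row))[1:]) + 1]
print(f"off-axis (tilt {tilt * 1e3:.0f} mrad): fringe period {period * 1e3:.1f} um, "
      f"expected lambda/sin(tilt) = {beam.wavelength / np.sin(tilt) * 1e3:.1f} um")
print("counting the fringe terminations at the axis would again give |l| = 5")
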