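# vortexmc

Coherent, polarization-tracking Monte Carlo simulation of Laguerre–Gaussian
(LG) vortex beams — structured light carrying orbital angular momentum
(OAM) — propagating through turbid, tissue-like slabs.

Light scattered many times in a turbid medium forms a speckle pattern, yet
the helical phase `exp(-i l phi)` that encodes a vortex beam's topological
charge `l` is surprisingly robust. `vortexmc` is built to study exactly
that: it transports photon packets through a slab (exponential free paths,
Henyey–Greenstein deflections with anisotropy `g`, Beer–Lambert
absorption, Snell/Fresnel boundaries), tracks each packet's optical-path
phase and a pair of real polarization vectors via the transverse
projection `P_i = [I - s_i ⊗ s_i] P_{i-1}` at every scattering event, and
sums the detected packets coherently per detector pixel:

    I_px = Σ W + 2 Σ_{i<j} √(W_i W_j) cos(Ψ_i − Ψ_j),
    ψ_px = atan2(Σ √W sin Ψ, Σ √W cos Ψ),

yielding intensity and phase speckle images of the transmitted (or
reflected) vortex beam. On top of the transport core it provides:

- analytic LG modes `LG_p^l` (field, phase with Gouy term, Poynting-vector
  skew launch directions), fork-hologram synthesis, and mode-faithful
  source sampling (rejection or stratified/quasi-random);
- interferogram synthesis against an expanded reference Gaussian (on-axis
  spirals / off-axis forked fringes);
- a numerical log-polar OAM sorter (two phase elements + lens transforms)
  that focuses each topological charge to a distinct lateral position and
  reads the charge back from the scattered field;
- the annular phase-memory statistic `R = |Σ I e^{i Δψ}| / Σ I`
  quantifying how much of the initial helical phase survives the medium;
- a scenario workbench (TOML configs, fixture grid of published phantom
  conditions, reproducibility manifests) and a thin `vortexmc` CLI.

Audience: researchers in biophotonics / tissue optics studying structured
light in scattering media, and anyone needing a coherent (phase-resolved)
photon Monte Carlo with polarization bookkeeping.

## Worked example

Transport an `LG_0^3` beam through a 1 mm slab with `mu_s = 4 mm^-1`,
`g = 0.8` and read the charge back from the transmitted speckle:

```python
import numpy as np
from vortexmc import (BeamSpec, MediumOptics, PixelGrid, RunConfig,
                      SorterGeometry, accumulate_image, run_transport,
                      sample_source, sort_field)

beam = BeamSpec(topological_charge=3, waist=0.8, wavelength=633e-6)  # mm
medium = MediumOptics(mus=4.0, mua=0.01, g=0.8, n=1.4, thickness=1.0)
print(medium.optical_depth)          # 0.8  (d/l*, transport mean free paths)

config = RunConfig(n_incident=400_000, n_detect=50_000,
                   detector_halfwidth=2.56, na=0.5, seed=77)
source = lambda n, rng: sample_source(beam, n, seed=rng, method="stratified")
result = run_transport(source, medium, config)
print(result.summary.detected)                  # 50000 detected photons
print(round(float(result.records.n_events.mean()), 2))   # 5.51 scattering events each

pair = accumulate_image(result.records, PixelGrid.centered(256, 0.02))
geom = SorterGeometry.for_grid(pair.grid, beam.wavelength)
res = sort_field(pair, geom, check_resolution=False)
peak = res.positions[np.argmax(res.profile)]
print(round(-peak / res.charge_spacing, 2))     # 2.88 — dominant lobe at l = 3
```

The printed numbers mean: the slab is 0.8 transport mean free paths thick;
detected photons scattered ~5.5 times on average, so the transmitted field
is a speckle pattern — yet the OAM sorter still focuses the dominant
intensity lobe at the `l = 3` position (2.88 charge spacings from the
Gaussian reference), i.e. the topological charge is retained through the
scattering medium. (For clean, unscattered modes `res.charge` snaps the
intensity centroid to the exact integer charge; for speckle the dominant
lobe is the meaningful readout.)

The `examples/` directory holds one short script per capability (beam
analytics, ballistic validation, slab speckle, OAM sorting, interferograms,
phase memory); each prints the numbers it computes and one line on what
they mean. The same workflows are scriptable from the shell:

```bash
vortexmc make-fixtures scenarios/          # published phantom conditions as TOML
vortexmc simulate scenarios/fig2-mus4.toml -o out/ --sorter --phase-memory
vortexmc sort --ell 2 -o profile.csv
```

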