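# Methods

`vortexmc` simulates the propagation of Laguerre–Gaussian (LG) vortex beams
— shaped light carrying orbital angular momentum (OAM) — through turbid,
tissue-like slabs, with a coherent, polarization-tracking Monte Carlo (MC)
photon model. This note records the model, its assumptions, the numerical
choices, and what the synthetic scenarios do and do not demonstrate.

## Beam model

The source is the paraxial LG mode `LG_p^l(rho, phi, z)` with the
`exp(-i l phi) exp(-i k z)` sign convention, normalized to unit transverse
power. Its phase is

    Psi = -k rho^2 z / (2 (z^2 + z_R^2)) - l phi - k z + G(z),
    G(z) = (2p + |l| + 1) arctan(z / z_R),

with `k = 2 pi / lambda` and Rayleigh range `z_R = pi w(0)^2 / lambda`.
For `p > 0` the generalized Laguerre polynomial changes sign on its nodal
rings and `arg(LG)` differs from the closed form by pi there; the closed
form is kept verbatim and the agreement property is asserted where the
radial envelope is positive (everywhere for `p = 0`, the only case the
slab scenarios use).

Each MC photon is launched with

- a transverse position drawn from `|LG|^2` at the launch plane
  (`z_launch = 0`, the waist placed at the medium entry — the launch
  distance is configurable but defaults to the waist since no other value
  is fixed by the scenario definitions);
- the mode phase at that point as its initial phase `psi_0`;
- the local Poynting-vector direction, whose Cartesian form is
  `s ∝ (k z x/(z^2+z_R^2) - l y/(x^2+y^2), k z y/(z^2+z_R^2) + l x/(x^2+y^2), k)`
  — the azimuthal term gives vortex rays their skew; the optical angular
  frequency is a pure scale factor and cancels under normalization. The
  on-axis singularity is excluded by a `rho < 1e-12 w0` guard band (the
  sampling density vanishes there anyway for `l != 0`);
- a polarization pair `P_x = a_x x̂⊥`, `P_y = a_y ŷ⊥` built from the
  Jones amplitudes `(a_x, a_y)` of the initial linear polarization
  (default horizontal: `(1, 0)`), with `x̂⊥` the lab x axis
  orthogonalized against the launch direction and `ŷ⊥` completing the
  triad. This normalization makes the ballistic detected weight equal the
  launched weight and the polarized/depolarized split exact (see below).

Two source samplers are provided. The default is rejection sampling
against the mode intensity. A stratified sampler maps scrambled-Sobol
points through the numerically inverted radial CDF; it is the standard
quasi-Monte Carlo variance reduction and is used wherever pixel-level
image fidelity matters (the ballistic validation needs per-pixel counts
far below Poisson noise: at 2^20 photons on a 128^2 grid the stratified
sampler reaches ~1.3% relative RMS where independent sampling would sit
near 7%).

## Slab and scattering model

The slab occupies `0 <= z <= d` and is characterized by the scattering
coefficient `mu_s` (per mm), absorption `mu_a`, Henyey–Greenstein (HG)
anisotropy `g`, and refractive index `n` inside an ambient index
`n_ambient`. Optical depth is quoted as `d/l*` with the transport mean
free path `l* = 1/(mu_s (1 - g))`: this is the definition that reproduces
the conventional labels of the tissue phantoms simulated here
(`d = 8 mm, mu_s = 6 mm^-1, g = 0.8 -> d/l* = 9.6`;
`d = 1 mm, mu_s = 10 mm^-1 -> d/l* = 2`), whereas `1/mu_s` would not.

Free paths are exponential, `l = -ln(xi)/mu_s`; the deflection cosine
comes from the closed-form HG inverse CDF (a table-lookup inverse is
available for arbitrary tabulated phase functions); the scattering
azimuth is uniform (HG has no azimuthal dependence). Weights attenuate by
Beer–Lambert `exp(-mu_a l)` per segment; the sampler assumes
`mu_a << mu_s` and warns otherwise. A configurable per-event scalar
`Gamma_R` (default 1.0) multiplies the weight at each scattering event.

At every scattering event both polarization vectors are projected onto
the plane transverse to the new direction,

    P_i = [I - s_i ⊗ s_i] P_{i-1},

without renormalization: the shrinkage of the pair is the model's
depolarization. The detected weight and its polarized/depolarized parts
are read from the lab-transverse components,

    W_par  = W0 (P_xx^2 + P_yx^2) Gamma^N exp(-mu_a sum l_i),
    W_perp = W0 (P_xy^2 + P_yy^2) Gamma^N exp(-mu_a sum l_i),
    W = W_par + W_perp  (identically),

so co/cross-polarized detection is bookkept per photon.

Boundaries apply Snell refraction and polarization-resolved Fresnel
coefficients: each P vector is decomposed into s/p components relative to
the plane of incidence, amplitude coefficients applied separately, and
the transmitted vectors carry the `sqrt(n2 cos t / n1 cos i)` power
factor so `|P_t|^2 + |P_r|^2 = |P|^2` per vector. At exactly normal
incidence the s/p frame is degenerate and the incident frame is reused
(the coefficients coincide). Beyond the critical angle the interface
totally reflects; the TIR phase shifts are not representable with real P
vectors and are dropped — a model limitation shared with the real-vector
polarization bookkeeping itself.

The engine selects the boundary branch probabilistically (transmit with
probability equal to the power transmittance of the current polarization
pair) and renormalizes the pair across the interface, which is unbiased
in expectation and keeps the per-photon weight ledger exact: detected +
absorbed + undetected-exit + entry-reflected + floor/cap-terminated
weight equals launched weight to rounding. Photons terminate when the
tracked weight (Beer–Lambert x Gamma) falls below 1e-4 or after 10^3
scattering events; Russian roulette is deliberately not used so the
termination rule stays a hard floor. With `mu_a << mu_s` the event cap is
the effective terminator — the weight floor matters only for absorbing
or `Gamma_R < 1` media.

### Phase accumulation

The propagation phase decreases by `k n l` per segment, matching the
`exp(-i k z)` convention of the analytic mode, so in the ballistic limit
the accumulated phase reproduces the closed-form free-space phase at the
exit plane exactly (`psi_0 - Psi_N = k n d` at normal incidence). This
optical-path rule is the standard choice in coherence-resolved MC; the
model neglects any phase structure of individual scattering events.

## Coherent detection

Exiting photons are detected on the transmission (`z = d`) or reflection
(`z = 0`) face if they land inside the square window `|x|,|y| <= r_d` and
within the acceptance cone `acos(s_N . s_d) < NA`, where `NA` is an
acceptance half-angle in radians compared directly against the exit
direction (not `n sin theta`), and `s_d` is the detector axis (optionally
tilted). Records accumulate per pixel through the complex sum
`A = sum sqrt(W) exp(i Psi)`; the coherent intensity `I = |A|^2` equals
the pairwise interference formula

    I_px = sum W + 2 sum_{i<j} sqrt(W_i W_j) cos(Psi_i - Psi_j)

(the pairwise form is kept as a test oracle), and the speckle phase is
`psi = arg A`, with a NaN mask where no photon landed (phase is undefined
there, not zero).

Two intensity estimators are exposed, because they converge to different
things:

- the **coherent** image `|A|^2` is the speckle realization — its
  expectation over random phases is the radiometric intensity, and its
  fluctuations are the speckle;
- the **weight-sum** image `sum W` is the radiometric estimator, correct
  for any photon population. For a deterministic (ballistic) population,
  where all phases in a pixel coincide, `|A|^2` grows like the squared
  photon count and is *not* an intensity estimate; the ballistic
  validation therefore compares the weight-sum image against the analytic
  mode, and the coherent image supplies the phase.

Interferograms are synthesized as `|E_s + E_r|^2` against an expanded
reference Gaussian (plane-wave-like, optional tilt): on-axis gives spiral
fringes whose arm count is the charge, off-axis gives forked straight
fringes of period `lambda / sin(tilt)`. Only synthesis is implemented —
no fringe demodulation.

## Phase-memory statistic

The retention of the helical phase is quantified on the bright annulus of
the mode (default radii `[0.7, 1.3] w(z) sqrt(l/2)`, recorded in output
metadata — the analysis region is not fixed by the source material):
per annulus pixel the wrapped difference `dpsi` between the measured
speckle phase and the free-space mode phase is formed, and the
intensity-weighted mean resultant length

    R = |sum I exp(i dpsi)| / sum I

is reported. `R -> 1` means the initial OAM phase modulation survives,
`R -> 0` means full scrambling. Intensity weighting suppresses
unreliable, sparsely occupied pixels.

One caveat discovered in validation and worth stating plainly: at high
optical depth the per-photon polarized weight spans many decades (its
depolarization factor decays roughly exponentially in the event count, and
detected event counts spread widely), so at desk-scale photon budgets the
intensity-weighted R collapses onto a handful of photons — the effective
pixel count of the d/l* = 9.6 run drops to single digits and R becomes
the resultant of a few random phasors (values near 1 with huge variance).
The phase-memory *fixtures* therefore bin the detected photons with
equalized (unit) weights before forming the statistic: the phase
structure, not the polarized-weight dynamic range, is what the statistic
probes, and with bounded weights its effective sample size is the
occupied-pixel count. At production budgets (>= 10^7 detections) the
distinction vanishes. The `phase_memory` function itself weights by
whatever intensity map it is given.

The fixture comparison uses a narrow acceptance cone (NA = 15 mrad): the
surviving helical phase lives in the quasi-ballistic component, and a
narrow cone is exactly how an imaging objective isolates it; with a wide
cone the diffuse background buries the coherent component at any feasible
photon budget. Replicate runs are pooled at the record level before
binning — quasi-ballistic photons share a deterministic phase and pool
coherently, the diffuse background pools incoherently — so the pooled R
carries the combined statistics of the seed replicates.

## Log-polar OAM sorter

Two phase-only elements in an f–f arrangement implement the Cartesian to
log-polar mapping:

    phi_1(x, y) = (2 pi a / lambda f) [ y atan2(y, x) - x ln(r/b) + x ],
    phi_2(u, v) = -(2 pi a b / lambda f) exp(-u/a) cos(v/a),

whose stationary-phase map sends `(x, y)` to `u = -a ln(r/b)`,
`v = a atan2(y, x)`: the helical phase `exp(-i l phi)` becomes a linear
gradient `exp(-i l v / a)` along the unwrapped strip, and the final lens
transform focuses each charge `lambda f / (2 pi a)` from its neighbour.
Propagation between elements is an idealized unitary lens Fourier
transform (FFT with orthonormal normalization), not free-space Fresnel
steps — the elements are treated as static phase masks in an f–f relay.
The output plane is zero-padded (factor 4) for sub-pixel centroid
precision; charge readout is the intensity-weighted centroid of the
lateral profile snapped to the nearest integer, ties toward zero. With
the `exp(-i l phi)` convention the spot displaces by `-l` spacings, and
the readout sign is fixed accordingly; the `l = 0` (Gaussian) spot
defines the reference position.

No sorter geometry is fixed by the source scenarios; the default scales
the transform to the grid (`a = n pitch / 16`,
`f = 2.6 pi a pitch / lambda`) so the unwrapped strip fits the Fourier
window with margin, and the values are recorded in the result. Inputs
must resolve the vortex rim (>= 8 pixels per phase fringe, checked);
MC speckle inputs are formed as `sqrt(I) exp(i psi)` per pixel, which
discards intra-pixel field structure — the resolution bottleneck for
MC-derived sorting, and the reason the speckle-input check may be
disabled for such images.

## Scenario grid and problem sizes

`make_fixtures` emits the scenario grid at desk scale: an LG_0^5 beam at
optical depths {0, 2.5, 5} (slab `mu_s` derived from `d/l*` with
g = 0.8), the LG_0^3 beam behind 1 mm slabs with
`mu_s = 2, 4, 6, 10 mm^-1` (`mu_a = 0.01 mm^-1`), the phantom pair
`d/l* = 2` vs `9.6`, and the `mu_s = 4, mu_a = 0.05` comparison slab; all
at 633 nm with a 0.8 mm waist. Values not fixed by the scenario
definitions (slab index n = 1.4, the `mu_a` of the phantom pair, the
1 mm thickness of the comparison slab) are flagged "default" in the TOML
files. Desk photon budgets are 10^6 launched / 5x10^4 detected per
scenario by default; the phase-memory comparison uses 4x10^6 (d/l* = 2)
and 8x10^6 (d/l* = 9.6) launched photons per replicate with an
index-matched slab, sizes chosen from a variance analysis so the pooled
5-replicate comparison resolves the memory contrast on a single CPU. Production-scale budgets (>= 10^9
launched, >= 10^7 detected) are valid configuration but are not exercised
by the test suite.

Reproducibility: one global seed expands into independent per-stage
streams (source chunks, transport chunks, realizations) via
`numpy.random.SeedSequence` keyed tuples; identical scenario + seed gives
bit-identical detection records and output files (SHA-256-verified
manifest round-trip).

## What the synthetic scenarios show — and what they do not

The generator emulates: coherent speckle formation from multiply
scattered partial waves, polarization memory loss, quasi-ballistic
survival of the helical phase, charge readout from scattered fields. It
does not emulate: real phantom microstructure (Mie phase functions with
azimuthal polarization coupling), interface roughness, detector noise,
finite temporal coherence, or the intra-pixel field structure lost when
re-synthesizing fields from binned images. Passing tests therefore
demonstrate internal consistency with the stated transport model and its
analytic limits, not quantitative agreement with any particular
experimental phantom.

## Known limitations

- Real-valued polarization vectors cannot carry circular/elliptical
  states or TIR/Fresnel phase shifts.
- The closed-form mode phase ignores the pi jumps at Laguerre nodes
  (`p > 0`).
- The coherent intensity estimator squares the photon density for
  deterministic populations (use the weight-sum image radiometrically).
- Single-realization speckle statistics at desk-scale budgets are noisy;
  ensemble statements need re-seeded realizations (`--realizations`).
- The sorter charge separation is the basic two-element design (~20%
  neighbour overlap); no fan-out refinement.
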