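# Methods

## Physical model

The assay holds a 48.5 kb λ-DNA between two surface tethers while buffer
flows perpendicular to the tether axis. An SMC motor extrudes a loop that
the flow stretches out of the tether plane; a dCas9-anchored nanoparticle
(30–200 nm) bound at a known site acts as a roadblock in a second imaging
channel. Whether the motor traps DNA pseudotopologically (through its ring)
or nontopologically (outside it) determines three observables after the
motor reaches the roadblock: the line-density multiplicity of the extruded
region (two co-extended loops at 4× the single-tether density vs one loop
at 2×), the roadblock's position relative to the loop stem (pinned vs
departing at the extrusion speed), and whether loop growth can continue
while the roadblock's MSD stays flat.

### Forces (`loopblock.mechanics`)

All forces are evaluated in the low-Reynolds, steady-drag limit:

* particle: `F = 6πηRv` with η = 1 mPa·s (aqueous buffer), R the particle
  **radius** in nm, v the flow speed in µm/s; at 79 µm/s this spans
  ~0.02 pN (30 nm particle) to just under 0.15 pN (200 nm).
* loop: `F = γ v L_c`, `L_c = α N · 0.34 nm` the contour length of the
  loop's N base pairs. γ defaults to 1·10⁻³ pN·s·µm⁻², deliberately at/below
  the 2–7·10⁻³ range reported for a 1 nm cylinder, appropriate for DNA
  aligned with the flow and conservative for the slippage argument (any
  larger γ strengthens the holding force of the large pre-encounter loop
  proportionally on both sides of the balance).
* thermal: the fluctuating force on a bead of friction Γ = 6πηR is
  delta-correlated with autocorrelation 2ΓkT·δ(τ); its RMS is finite only
  over a bandwidth, and we report `√(2ΓkT/T_avg)` with a 1 s default
  averaging window (frame scale). For R = 10 nm at 298 K this is ≈1.2 fN —
  four orders of magnitude below the drag forces, so thermal motion cannot
  un-pin a trapped roadblock. The "10 nm particle" convention is read as a
  radius; reading it as a diameter halves Γ and changes nothing
  qualitatively. kT is derived from the temperature (298 K default) unless
  overridden; α defaults to 1 (no intercalator correction) and is
  configurable.
* slippage: DNA transfers from the held loop-1 into the growing loop-2 only
  if `F_loop2 + F_particle > F_loop1` **strictly**; exact equality does not
  slip, because slippage requires the opposing force to exceed the holding
  force. With the typical 12 kb (up to 24 kb) loop-1 against a ≤6 kb loop-2
  and a 39 nm particle, the balance never fires.

## Synthetic data (`loopblock.synthetic`)

The generator is a *stylized observable-level* emulation, not a polymer
simulation. Its defaults are the study conditions: genome 48.5 kb,
extrusion 0.5 kb/s, encounter at a 12 kb loop, 6 kb extruded afterwards,
flow 79 µm/s, 39 nm roadblock, 0.108 µm/px, 0.5 s frames.

**Geometry.** Tether anchors sit on a horizontal line; flow points +y. The
stem (motor position) is a fixed point below the tether axis; the loop is a
straight vertical extension from the stem with its two arms co-linear and
unresolved. On-screen length maps to DNA through a flow-stretch fraction:
1 kb of stretched DNA occupies `stretch_fraction × 0.34 µm`. The default
0.412 is calibrated so that a 30 kb loop (15 kb per arm) is 2.10 µm long
and a 24 kb loop 1.68 µm — the extensions observed for flow-stretched
encounter events. The motor-distal tether arm is rendered taut at exactly
this stretch; slack on the roadblock-side arm is drawn as a straight chord
of proportionally higher line density. This keeps three properties exact by
construction: photons are conserved frame to frame (deposition is
proportional to base pairs), the taut arm has exactly 1-strand line
density, and the loop (2-strand) and doubled-loop (4-strand) regions are
exactly 2× and 4× that density. Extrusion is one-sided, toward the
roadblock, so all post-encounter DNA feeds the roadblock's arm.

**Kinematics.** Both mechanisms are identical before the encounter (the
roadblock is reeled toward the stem). Afterwards: nontopological — one loop
keeps growing and the roadblock's stem distance is the extension of the DNA
added after encounter, `(added / (total/2)) · loop_length`, i.e. it departs
at `stretch × 0.34 µm/kb × rate` ≈ 0.07 µm/s for 0.5 kb/s;
pseudotopological — loop-1 freezes, loop-2 grows, the roadblock stays at
distance 0 unless the mechanics force balance fires, in which case the
loops merge abruptly. Growth stops when the configured total is reached
(loop disruption / DNA exhaustion); stall intervals can zero the rate.

**Rendering.** Photons (default 200 per kb per frame, chosen to give
roughly percent-level per-frame fractional noise on the total DNA signal)
are deposited bilinearly along each segment, convolved with a Gaussian PSF
(σ = 1 px), then Poisson shot noise, a camera baseline (100 counts), and
Gaussian read noise (σ = 2) are applied, clipping at zero. The baseline
keeps the clipped counts unbiased; background subtraction removes it
downstream. Per-frame noise streams are spawned deterministically from one
seed. The roadblock channel holds a PSF-shaped spot at the roadblock
position; localization tables emulate a spot tracker as ground truth plus
0.5 px Gaussian error.

**Stall events** (no side flow) are generated directly at the observable
level: the windowed MSD of the roadblock plateaus at a level proportional
to the squared extension of its confining arm — half the growing loop
(nontopological) or half the frozen loop-1 (pseudotopological) — with 5 %
multiplicative noise, alongside the measured total loop size with 0.5 kb
additive noise.

**What the generator does not emulate:** polymer fluctuations and loop
conformation, photobleaching, dCas9 binding kinetics, tether-point drift,
camera vignetting, steric detail of large roadblocks, and the manual
variability of hand-drawn contours. Passing recovery tests therefore
demonstrates correctness of the measurement and decision logic under the
stated noise model, not robustness to every artifact of real movies.

## Measurements (`loopblock.quantify`)

* **Profiles**: mean transverse intensity over an 11 px-wide box along a
  polyline, minus a scalar background (median outside an Otsu-thresholded,
  dilated foreground mask — the thresholding is a documented choice, as
  manual line tools leave background estimation unspecified).
* **Loop size**: `genome_kb · I_loop/I_total` (scale-invariant by
  construction). On synthetic frames `I_loop` is the fractional-row sum of
  the field beyond the stem; a first-order PSF correction subtracts
  `0.399σ(ρ_above − ρ_below)` — the net flux a half-plane sum gains across
  the boundary — with the line densities ρ measured ~3σ on either side.
  This brings the bias below ~0.1 kb for loops ≥ 6 kb. Stem positions can
  be supplied per frame (the programmatic stand-in for manually drawn
  annotations; ground truth in synthetic runs) or auto-detected from the
  intensity ridge at a few-pixel accuracy.
* **Extrusion rate**: centered 20-point rolling mean of the loop-size
  series, first-differenced; edges are truncated (reported missing) rather
  than padded, so no rates are fabricated at the series ends.
* **MSD**: time-averaged over all valid frame pairs per lag
  (overlapping-pair estimator), with NaN localization gaps excluded
  pair-wise; validated against brute-force pair enumeration.
* **Flow speed**: instantaneous speeds from successive fly-by localizations,
  averaged per track, then pooled across tracks (mean, SD, n).

## Decision rules (`loopblock.discriminate`)

Each verdict is a pure function of its reported statistics, so every call
is auditable from the report alone.

* **P1**: peak of the 3-point-smoothed post-encounter loop profile over the
  1× tether level, with the pre-encounter loop checked to be ~2× (within
  25 %). Threshold 3.0 — the midpoint between I_2x and I_4x; profiles with
  SNR < 3 or no visible loop (< 1.5×) are inconclusive.
* **P2**: pinned if the roadblock-stem distance stays under 2 px (0.216 µm)
  in ≥ 90 % of post-encounter frames (a robust version of "stays at the
  stem throughout" that single localization outliers cannot flip);
  departing if the distance rises monotonically (Spearman ρ ≥ 0.7) at a
  speed within a factor band [0.5, 2] of the extrusion speed, the latter
  converted to µm/s through the measured arm extension per kb. Fits use
  only frames where the loop is still growing. The encounter itself is
  detected operationally as colocalization within 2 px for ≥ 2 frames.
* **P3**: stall windows are intervals where the 5-point-smoothed MSD varies
  by < 20 % (relative) for ≥ 10 s. Within each window (edge-trimmed by the
  smoothing width, since plateau boundaries are only resolved to that
  scale) loop growth is tested with a one-sided slope test at α = 0.05
  **and** a practical-significance floor of 1.5 kb fitted growth — ~3× the
  loop-size measurement noise — so that flat-but-noisy series are not
  scored as growth. Any stall with significant growth supports the
  pseudotopological reading; stalls without, the nontopological one.
* **Aggregate**: majority over conclusive verdicts; ties and all-inconclusive
  sets stay inconclusive.

## Problem sizes and numerical choices

Validation studies run at deliberately compact sizes: 64×64 px movies of
~90 frames, 20 fly-by tracks of 10 frames for flow-speed recovery, 10
seeded movies for loop-size bias, 15 seeded stall events for P3, and 2×20
seeded end-to-end runs for discrimination accuracy. Coordinates follow
pixel centers at integer (row, col); physical (x, y) positions are µm with
x along the tether axis. All RNG streams derive from a single seed via
spawned `SeedSequence`s, making every pipeline output byte-reproducible.

## Known limitations

* The stylized geometry renders the slack tether arm as a brighter straight
  chord rather than a bowed arc; profile baselines should therefore be read
  from the taut arm (the pipeline does).
* Auto-detected stem positions are only accurate to a few pixels near the
  arm/loop junction; quantitative loop sizing should use supplied stem
  annotations, mirroring the manual workflow of real analyses.
* The P3 observables are generated directly (confinement-scaled MSD), not
  derived from simulated Brownian trajectories; the test validates the
  plateau/growth logic, not MSD estimation from raw no-flow tracks (which
  `msd_curve` covers separately).
* Slippage, when triggered, is modeled as a single abrupt merge; partial or
  repeated slippage is out of scope.
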