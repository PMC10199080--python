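# loopblock

Quantitative analysis for **SMC roadblock-encounter experiments**: does a
loop-extruding SMC complex (condensin, cohesin) thread DNA through its ring
(*pseudotopological* extrusion) or hold it on the outside (*nontopological*
extrusion)? The two mechanisms make sharply different predictions for what
happens when the motor runs into a large DNA-bound roadblock — here a
dCas9-anchored nanoparticle (30–200 nm) on double-tethered λ-DNA (48.5 kb),
visualized by stretching the extruded loop with a perpendicular buffer flow
("side flow", ~79 µm/s).

`loopblock` implements the whole observable-level argument as a tested
pipeline:

* **mechanics** — closed-form force balance on the flow-stretched system:
  Stokes drag on the particle `F = 6πηRv`, drag on a loop of `N` bp
  `F = γ v L_c` with `L_c = αN·0.34 nm`, the RMS thermal force
  `√(2·6πηR·kT/T_avg)`, and the slippage condition
  `F_loop2 + F_particle > F_loop1`.
* **synthetic** — a ground-truth generator: extrusion kinematics under
  either mechanism and calibrated two-channel movies (DNA + roadblock,
  0.108 µm/px, Poisson shot + Gaussian read noise) emulating the side-flow
  assay, so every measurement stage is testable by parameter recovery.
* **quantify** — the measurement procedures: background-subtracted
  intensity profiles along drawn contours (11 px boxes), loop size
  `48.5 kb · I_loop/I_total`, roadblock–stem distances, 20-point
  rolling-mean extrusion rates, time-averaged MSD curves, and flow-speed
  estimation from fly-by particles.
* **discriminate** — the three prediction tests and a per-event model call:
  * **P1** intensity multiplicity: a blocked loop merge leaves *two*
    co-extended loops, i.e. a 4× line density (I_4x) instead of the 2×
    (I_2x) of a single loop;
  * **P2** stem residence: a trapped roadblock stays at the loop stem,
    whereas nontopological passage makes it depart into the loop at the
    extrusion speed (e.g. 6 kb/15 kb · 2.1 µm = 0.84 µm expected travel);
  * **P3** stall coupling: without flow, a trapped roadblock's MSD can
    plateau while the loop keeps growing; nontopologically, loop size and
    MSD stall together.
* **io / cli** — TIFF/CSV/JSON round-trips and the `loopblock` command with
  `simulate`, `quantify`, `discriminate`, `forces`, and `run` subcommands.

## Worked example

The force balance for the typical encounter — a 24 kb loop holding against
a 6 kb second loop plus a 39 nm particle at 79 µm/s:

```bash
$ loopblock forces --particle-nm 39 --loop1-kb 24 --loop2-kb 6 --flow-um-s 79
{
  "f_loop1_pn": 0.6446400000000002,
  "f_loop2_pn": 0.16116000000000005,
  "f_particle_pn": 0.029037740897130456,
  "flow_um_s": 79.0,
  "slips": false
}
```

The drag holding the first loop (~0.65 pN) dwarfs the ~0.16 + 0.03 pN
pulling on the second loop and particle, so a pseudotopologically trapped
roadblock could not slip free — it would have to sit at the loop stem.

A full synthetic event, simulated under the nontopological mechanism and
pushed through measurement and all three prediction tests:

```bash
$ loopblock run --model nontopological --seed 1 --out demo
aggregate call: nontopological

$ cat demo/summary.txt
loopblock 0.1.0 run eccdd2478ff6 (seed 1)
aggregate model call: nontopological
  P1: supports_nontopological
  P2: supports_nontopological
  P3: supports_nontopological
```

`demo/report.json` carries the statistics behind each outcome: the
post-encounter profile peaks at 2.0× the tether level (a single loop, not
the 4× a double loop would show), the roadblock departs the stem at a speed
comparable to the extrusion speed, and the MSD stall window shows no
concurrent loop growth. Simulating with `--model pseudotopological` flips
all three outcomes.

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generator's geometry and noise model, the decision rules with their
thresholds, and known limitations.
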