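"""Synthetic side-flow roadblock-encounter movies with known ground truth.

This module generates the study conditions end to end: per-frame extrusion
kinematics under either a pseudotopological or a nontopological
loop-extrusion model, and calibrated two-channel fluorescence movies (DNA +
roadblock) that emulate a side-flow single-molecule assay on double-tethered
lambda-DNA (48.5 kb). Every downstream measurement and model-discrimination
stage can therefore be validated by parameter recovery without any external
data.

Geometry (stylized, not a polymer simulation)
---------------------------------------------
The two tether anchors sit on a horizontal line; buffer flow points "down"
(+y). The SMC motor sits at a fixed stem point below the tether axis; the
extruded loop is rendered as a straight vertical extension from the stem,
with its two arms co-linear and unresolved (2 DNA strands per unit length).
When the pseudotopological model traps the roadblock, the frozen first loop
and the growing second loop co-extend from the stem, giving a 4-strand
region. The tether arm on the motor-distal side is rendered taut at the
flow-stretch extension; slack on the roadblock side is drawn as a straight
chord of correspondingly higher line density. Photons are deposited in
proportion to base pairs, so the total expected DNA-channel intensity is
conserved from frame to frame and noiseless line densities are exactly
1:2:4 (single tether : loop : doubled loop).

Extrusion is one-sided (toward the roadblock), at a default 0.5 kb/s; the
roadblock is a dCas9-anchored nanoparticle (default 39 nm) imaged in a
second channel. Defaults for flow (79 µm/s), pixel size (0.108 µm/px),
encounter loop size (12 kb) and post-encounter extrusion (6 kb) follow the
typical values measured in such assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import mechanics
from .errors import InvalidArgumentError, OutOfFieldError

__all__ = [
    "PSEUDOTOPOLOGICAL",
    "NONTOPOLOGICAL",
    "SimulationConfig",
    "OpticsConfig",
    "ExtrusionKinematics",
    "MovieStack",
    "simulate_kinematics",
    "render_movie",
    "make_flyby_tracks",
    "roadblock_track",
    "simulate_stall_event",
    "label_stages",
]

PSEUDOTOPOLOGICAL = "pseudotopological"
NONTOPOLOGICAL = "nontopological"
_MODELS = (PSEUDOTOPOLOGICAL, NONTOPOLOGICAL)

#: Contour length of 1 kb of B-DNA in µm (1000 bp x 0.34 nm).
UM_PER_KB_CONTOUR = 0.34


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated roadblock-encounter event.

    ``encounter_loop_kb`` is the loop size when the motor reaches the
    roadblock; ``post_encounter_kb`` is how much more DNA is extruded
    afterwards. ``stall_intervals`` lists (start_s, stop_s) windows during
    which the extrusion rate drops to zero (used for stall-event studies).
    ``loop_start_s`` delays loop nucleation so movies begin with "No Loop"
    frames. ``n_frames=None`` sizes the movie to cover the full event plus
    a short tail.
    """

    model: str
    genome_kb: float = 48.5
    extrusion_rate_kb_s: float = 0.5
    encounter_loop_kb: float = 12.0
    post_encounter_kb: float = 6.0
    flow_speed_um_s: float = 79.0
    frame_interval_s: float = 0.5
    n_frames: int | None = None
    seed: int = 0
    roadblock_diameter_nm: float = 39.0
    loop_start_s: float = 4.0
    stall_intervals: tuple = ()

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise InvalidArgumentError(f"model must be one of {_MODELS}, got {self.model!r}")
        for name in ("genome_kb", "frame_interval_s", "roadblock_diameter_nm"):
            if not getattr(self, name) > 0.0:
                raise InvalidArgumentError(f"{name} must be > 0")
        for name in (
            "extrusion_rate_kb_s",
            "encounter_loop_kb",
            "post_encounter_kb",
            "flow_speed_um_s",
            "loop_start_s",
        ):
            if getattr(self, name) < 0.0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.encounter_loop_kb + self.post_encounter_kb > self.genome_kb:
            raise InvalidArgumentError(
                "encounter_loop_kb + post_encounter_kb must not exceed genome_kb"
            )
        if self.post_encounter_kb > self.encounter_loop_kb:
            raise InvalidArgumentError(
                "post_encounter_kb must not exceed encounter_loop_kb "
                "(the roadblock would pass the loop tip)"
            )
        if self.n_frames is not None and self.n_frames < 1:
            raise InvalidArgumentError("n_frames must be >= 1")
        for iv in self.stall_intervals:
            if len(iv) != 2 or iv[1] <= iv[0]:
                raise InvalidArgumentError(f"bad stall interval {iv!r}")


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging calibration and rendering parameters.

    ``stretch_fraction`` maps DNA contour to on-screen length under side
    flow (loop arm extension = stretch_fraction x contour of the arm); the
    default 0.412 makes a 30 kb loop 2.10 µm long and a 24 kb loop 1.68 µm,
    the extensions seen in flow-stretched encounter events.
    ``photons_per_kb`` is the expected DNA-channel photon yield per kb per
    frame; shot noise is Poissonian on top of it, plus Gaussian read noise.
    """

    pixel_size_um: float = 0.108
    psf_sigma_px: float = 1.0
    photons_per_kb: float = 200.0
    read_noise: float = 2.0
    image_shape: tuple = (64, 64)
    tether_separation_um: float = 2.2
    stretch_fraction: float = 0.412
    roadblock_photons: float = 3000.0
    anchor_y_um: float = 0.9
    camera_offset: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "psf_sigma_px",
            "photons_per_kb",
            "roadblock_photons",
            "tether_separation_um",
        ):
            if not getattr(self, name) > 0.0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if not 0.0 < self.stretch_fraction <= 1.0:
            raise InvalidArgumentError("stretch_fraction must be in (0, 1]")
        if self.read_noise < 0.0 or self.camera_offset < 0.0:
            raise InvalidArgumentError("read_noise and camera_offset must be >= 0")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise InvalidArgumentError("image_shape must be (rows, cols) with rows, cols >= 8")

    @property
    def um_per_kb(self) -> float:
        """On-screen extension of 1 kb of flow-stretched DNA, µm."""
        return self.stretch_fraction * UM_PER_KB_CONTOUR

    def um_to_px(self, um):
        return np.asarray(um, dtype=float) / self.pixel_size_um

    def px_to_um(self, px):
        return np.asarray(px, dtype=float) * self.pixel_size_um


@dataclass
class ExtrusionKinematics:
    """Per-frame ground truth of one simulated event.

    ``frames`` columns (units in names): time_s, loop1_kb, loop2_kb,
    total_loop_kb, loop_length_um, arm1_kb, arm2_kb, roadblock_genomic_kb,
    roadblock_x_um, roadblock_y_um, stem_x_um, stem_y_um, slipped.
    ``geometry`` records the anchor/stem positions and the kb->µm mapping
    used, so a renderer can reproduce the scene exactly.
    """

    frames: pd.DataFrame
    encounter_frame: int | None
    config: SimulationConfig
    geometry: dict

    def __len__(self) -> int:
        return len(self.frames)

    def measurement_series(self) -> pd.DataFrame:
        """Noise-free measurement table in the layout produced by
        :func:`loopblock.quantify.measure_loop_series` (time, loop size,
        loop length, stem position, roadblock-stem distance)."""
        f = self.frames
        dist = np.hypot(
            f["roadblock_x_um"] - f["stem_x_um"], f["roadblock_y_um"] - f["stem_y_um"]
        )
        return pd.DataFrame(
            {
                "time_s": f["time_s"],
                "loop_kb": f["total_loop_kb"],
                "loop_length_um": f["loop_length_um"],
                "stem_x_um": f["stem_x_um"],
                "stem_y_um": f["stem_y_um"],
                "roadblock_distance_um": dist,
            }
        )


@dataclass
class MovieStack:
    """Two-channel image time series with shared calibration.

    ``dna`` and ``roadblock`` are float32 arrays of shape
    (frames, rows, cols); intensities are photon counts (non-negative).
    """

    dna: np.ndarray
    roadblock: np.ndarray
    optics: OpticsConfig
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.dna.shape != self.roadblock.shape or self.dna.ndim != 3:
            raise InvalidArgumentError("dna and roadblock channels must share (T, H, W) shape")
        if self.frame_interval_s <= 0.0:
            raise InvalidArgumentError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.dna.shape[0]


def _effective_extrusion_time(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Seconds of active extrusion elapsed at each frame time (stalls excluded)."""
    eff = np.clip(t - config.loop_start_s, 0.0, None)
    for t0, t1 in config.stall_intervals:
        lo = max(t0, config.loop_start_s)
        overlap = np.clip(np.minimum(t, t1) - lo, 0.0, None)
        eff = eff - overlap
    return np.clip(eff, 0.0, None)


def simulate_kinematics(
    config: SimulationConfig,
    optics: OpticsConfig | None = None,
    params: mechanics.PhysicalParams | None = None,
) -> ExtrusionKinematics:
    """Generate per-frame ground-truth kinematics for one encounter event.

    Both models are identical before the encounter: a single loop grows at
    the extrusion rate while the roadblock is reeled toward the stem. After
    the encounter the nontopological model keeps growing one loop and the
    roadblock moves into it (distance from stem = extension of the DNA added
    after encounter); the pseudotopological model freezes loop-1, grows
    loop-2, and pins the roadblock at the stem — unless the
    :func:`loopblock.mechanics.slippage_check` force balance fires, in which
    case the loops merge abruptly and the event continues nontopologically.
    """
    optics = optics or OpticsConfig()
    params = params or mechanics.PhysicalParams()
    cfg = config

    final_total = cfg.encounter_loop_kb + cfg.post_encounter_kb
    arm1_kb = (cfg.genome_kb - final_total) / 2.0  # motor-distal tether arm, constant
    upk = optics.um_per_kb
    arm1_len_um = upk * arm1_kb
    half_sep = optics.tether_separation_um / 2.0
    if arm1_len_um <= half_sep:
        raise InvalidArgumentError(
            "tethered DNA too short for the tether separation: decrease "
            "tether_separation_um or the total extruded amount"
        )
    stem_depth_um = math.sqrt(arm1_len_um**2 - half_sep**2)

    height_um, width_um = (
        optics.image_shape[0] * optics.pixel_size_um,
        optics.image_shape[1] * optics.pixel_size_um,
    )
    x_c = width_um / 2.0
    y0 = optics.anchor_y_um
    anchor1 = (x_c - half_sep, y0)
    anchor2 = (x_c + half_sep, y0)
    stem = (x_c, y0 + stem_depth_um)

    if cfg.n_frames is None:
        if cfg.extrusion_rate_kb_s > 0.0:
            stall_s = sum(t1 - t0 for t0, t1 in cfg.stall_intervals)
            span = cfg.loop_start_s + final_total / cfg.extrusion_rate_kb_s + stall_s
            n_frames = int(math.ceil(span / cfg.frame_interval_s)) + 10
        else:
            n_frames = 20
    else:
        n_frames = cfg.n_frames

    t = np.arange(n_frames) * cfg.frame_interval_s
    total = np.minimum(cfg.extrusion_rate_kb_s * _effective_extrusion_time(t, cfg), final_total)

    enc_idx = np.nonzero(total >= cfg.encounter_loop_kb - 1e-12)[0]
    encounter_frame = int(enc_idx[0]) if enc_idx.size else None

    loop1 = np.array(total)
    loop2 = np.zeros_like(total)
    dist = np.zeros_like(total)
    slipped = np.zeros(n_frames, dtype=bool)

    post = encounter_frame is not None
    if post:
        after = np.arange(n_frames) >= encounter_frame
        added = np.where(after, total - cfg.encounter_loop_kb, 0.0)
        if cfg.model == NONTOPOLOGICAL:
            dist = upk * added
        else:
            loop1 = np.where(after, cfg.encounter_loop_kb, total)
            loop2 = np.where(after, added, 0.0)
            # per-frame force balance; merge abruptly if loop-2 + particle drag wins
            merged = False
            for i in range(encounter_frame, n_frames):
                if not merged:
                    fb = mechanics.slippage_check(
                        loop1[i],
                        loop2[i],
                        cfg.roadblock_diameter_nm / 2.0,
                        cfg.flow_speed_um_s,
                        params,
                    )
                    merged = fb.slips
                if merged:
                    slipped[i] = True
                    loop1[i] = total[i]
                    loop2[i] = 0.0
                    dist[i] = upk * added[i]

    arm2_kb = cfg.genome_kb - arm1_kb - total  # roadblock-side tether arm
    loop_len = upk * total / 2.0

    # roadblock position: on the arm-2 chord before encounter, inside the loop after
    gap_kb = np.clip(cfg.encounter_loop_kb - total, 0.0, None)
    frac = np.divide(gap_kb, arm2_kb, out=np.zeros_like(gap_kb), where=arm2_kb > 0)
    rb_x = stem[0] + frac * (anchor2[0] - stem[0])
    rb_y = stem[1] + frac * (anchor2[1] - stem[1])
    inside = total >= cfg.encounter_loop_kb - 1e-12
    rb_x = np.where(inside, stem[0], rb_x)
    rb_y = np.where(inside, stem[1] + dist, rb_y)

    frames = pd.DataFrame(
        {
            "time_s": t,
            "loop1_kb": loop1,
            "loop2_kb": loop2,
            "total_loop_kb": total,
            "loop_length_um": loop_len,
            "arm1_kb": np.full(n_frames, arm1_kb),
            "arm2_kb": arm2_kb,
            "roadblock_genomic_kb": np.full(n_frames, arm1_kb + cfg.encounter_loop_kb),
            "roadblock_x_um": rb_x,
            "roadblock_y_um": rb_y,
            "stem_x_um": np.full(n_frames, stem[0]),
            "stem_y_um": np.full(n_frames, stem[1]),
            "slipped": slipped,
        }
    )
    geometry = {
        "anchor1_um": anchor1,
        "anchor2_um": anchor2,
        "stem_um": stem,
        "um_per_kb": upk,
        "field_um": (height_um, width_um),
    }
    return ExtrusionKinematics(
        frames=frames, encounter_frame=encounter_frame, config=cfg, geometry=geometry
    )


def _deposit_point(img: np.ndarray, x_px: float, y_px: float, photons: float) -> None:
    """Bilinear splat of ``photons`` at sub-pixel position (pixel centers at integers)."""
    r0, c0 = int(np.floor(y_px)), int(np.floor(x_px))
    fr, fc = y_px - r0, x_px - c0
    h, w = img.shape
    for dr, wr in ((0, 1.0 - fr), (1, fr)):
        for dc, wc in ((0, 1.0 - fc), (1, fc)):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < h and 0 <= c < w and wr * wc > 0.0:
                img[r, c] += photons * wr * wc


def _deposit_segment(
    img: np.ndarray, p0, p1, photons: float, pixel_size_um: float, step_um: float = 0.02
) -> None:
    """Deposit ``photons`` uniformly along the segment p0 -> p1 (µm coordinates)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(2, int(math.ceil(length / step_um)) + 1)
    xs = np.linspace(p0[0], p1[0], n) / pixel_size_um
    ys = np.linspace(p0[1], p1[1], n) / pixel_size_um
    per_point = photons / n
    c0 = np.floor(xs).astype(np.intp)
    r0 = np.floor(ys).astype(np.intp)
    fc = xs - c0
    fr = ys - r0
    h, w = img.shape
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        r = r0 + dr
        c = c0 + dc
        ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
        np.add.at(img, (r[ok], c[ok]), per_point * wt[ok])


def _frame_segments(row: pd.Series, geometry: dict, upk: float):
    """DNA segments (p0_um, p1_um, kb) for one kinematics frame."""
    a1 = geometry["anchor1_um"]
    a2 = geometry["anchor2_um"]
    stem = geometry["stem_um"]
    segs = [(a1, stem, row["arm1_kb"]), (a2, stem, row["arm2_kb"])]
    for kb in (row["loop1_kb"], row["loop2_kb"]):
        if kb > 0.0:
            tip = (stem[0], stem[1] + upk * kb / 2.0)
            segs.append((stem, tip, kb))
    return segs


def render_movie(
    kin: ExtrusionKinematics,
    optics: OpticsConfig | None = None,
    seed: int | None = None,
    noise: bool = True,
) -> MovieStack:
    """Render a two-channel movie from ground-truth kinematics.

    The DNA channel deposits ``photons_per_kb`` photons per kb along each
    segment (tether arms, loop, co-extended second loop), convolves with a
    Gaussian PSF, and — when ``noise`` is on — applies Poisson shot noise
    followed by additive Gaussian read noise (clipped at zero, as an offset
    camera would). The roadblock channel renders a PSF-shaped spot at the
    roadblock position. Expected total DNA-channel intensity per frame is
    proportional to the genome size regardless of loop state.
    """
    optics = optics or OpticsConfig()
    shape = tuple(optics.image_shape)
    n = len(kin)
    upk = kin.geometry["um_per_kb"]
    h_um = shape[0] * optics.pixel_size_um
    w_um = shape[1] * optics.pixel_size_um

    dna = np.zeros((n,) + shape, dtype=np.float64)
    rb = np.zeros_like(dna)
    margin = 3.0 * optics.psf_sigma_px * optics.pixel_size_um

    for i, (_, row) in enumerate(kin.frames.iterrows()):
        segs = _frame_segments(row, kin.geometry, upk)
        pts = [p for seg in segs for p in seg[:2]]
        pts.append((row["roadblock_x_um"], row["roadblock_y_um"]))
        for x, y in pts:
            if not (margin <= x <= w_um - margin and margin <= y <= h_um - margin):
                raise OutOfFieldError(
                    f"frame {i}: position ({x:.2f}, {y:.2f}) µm outside the "
                    f"{h_um:.2f} x {w_um:.2f} µm field (3-sigma PSF margin)"
                )
        for p0, p1, kb in segs:
            _deposit_segment(dna[i], p0, p1, kb * optics.photons_per_kb, optics.pixel_size_um)
        _deposit_point(
            rb[i],
            row["roadblock_x_um"] / optics.pixel_size_um,
            row["roadblock_y_um"] / optics.pixel_size_um,
            optics.roadblock_photons,
        )
        dna[i] = gaussian_filter(dna[i], optics.psf_sigma_px, mode="constant")
        rb[i] = gaussian_filter(rb[i], optics.psf_sigma_px, mode="constant")

    if noise:
        ss = np.random.SeedSequence(kin.config.seed if seed is None else seed)
        children = ss.spawn(n)
        for i in range(n):
            rng = np.random.default_rng(children[i])
            for chan in (dna, rb):
                # camera baseline keeps the zero-clipped counts unbiased;
                # background subtraction removes it downstream
                noisy = rng.poisson(chan[i]).astype(np.float64) + optics.camera_offset
                noisy += rng.normal(0.0, optics.read_noise, size=shape)
                chan[i] = np.clip(noisy, 0.0, None)

    return MovieStack(
        dna=dna.astype(np.float32),
        roadblock=rb.astype(np.float32),
        optics=optics,
        frame_interval_s=kin.config.frame_interval_s,
    )


def make_flyby_tracks(
    true_speed_um_s: float,
    n_particles: int = 20,
    frames_per_particle: int = 10,
    localization_noise_px: float = 0.5,
    frame_interval_s: float = 0.05,
    pixel_size_um: float = 0.108,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate fly-by particle localizations for flow-speed calibration.

    Untethered particles advect along the flow axis (+y) at ``true_speed``;
    localizations carry isotropic Gaussian error of ``localization_noise_px``
    pixels. Returns a table with columns particle, frame, time_s, x_um, y_um.
    """
    if true_speed_um_s < 0.0:
        raise InvalidArgumentError("true_speed_um_s must be >= 0")
    if n_particles < 1 or frames_per_particle < 2:
        raise InvalidArgumentError("need n_particles >= 1 and frames_per_particle >= 2")
    if localization_noise_px < 0.0:
        raise InvalidArgumentError("localization_noise_px must be >= 0")
    rng = np.random.default_rng(seed)
    sigma_um = localization_noise_px * pixel_size_um
    records = []
    for p in range(n_particles):
        x0 = rng.uniform(0.0, 20.0)
        y0 = rng.uniform(0.0, 2.0)
        for f in range(frames_per_particle):
            t = f * frame_interval_s
            records.append(
                {
                    "particle": p,
                    "frame": f,
                    "time_s": t,
                    "x_um": x0 + rng.normal(0.0, sigma_um),
                    "y_um": y0 + true_speed_um_s * t + rng.normal(0.0, sigma_um),
                }
            )
    return pd.DataFrame(records)


def roadblock_track(
    kin: ExtrusionKinematics,
    localization_noise_px: float = 0.5,
    pixel_size_um: float = 0.108,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-frame roadblock localizations with Gaussian localization error.

    Emulates the localization table a spot tracker would produce from the
    roadblock channel; ground truth comes from the kinematics.
    """
    rng = np.random.default_rng(seed)
    sigma_um = localization_noise_px * pixel_size_um
    f = kin.frames
    n = len(f)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": f["time_s"].to_numpy(),
            "x_um": f["roadblock_x_um"].to_numpy() + rng.normal(0.0, sigma_um, n),
            "y_um": f["roadblock_y_um"].to_numpy() + rng.normal(0.0, sigma_um, n),
        }
    )


def simulate_stall_event(
    model: str,
    extrusion_rate_kb_s: float = 0.5,
    initial_loop_kb: float = 4.0,
    encounter_loop_kb: float = 12.0,
    frame_interval_s: float = 1.0,
    n_frames: int = 70,
    stall_start_s: float = 40.0,
    stall_duration_s: float = 20.0,
    loop_noise_kb: float = 0.5,
    msd_noise_frac: float = 0.05,
    msd_scale: float = 0.3,
    um_per_kb: float = 0.412 * UM_PER_KB_CONTOUR,
    max_loop_kb: float = 30.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Loop-size and windowed-MSD observables of a no-flow stall event.

    Without side flow, the positional freedom of a roadblock scales with the
    DNA tether available to it, so its windowed MSD plateaus at a level
    proportional to the squared extension of its confining arm. Under the
    nontopological model that arm is half of the (single) growing loop: MSD
    is flat only while extrusion is stalled. Under the pseudotopological
    model the roadblock stays pinned with frozen loop-1 after the encounter:
    MSD is flat from the encounter on, *while the measured loop size keeps
    growing* — the observable contrast the stall-event test exploits.

    Returns columns time_s, loop_kb (measured total, with Gaussian noise),
    msd_um2 (with multiplicative noise), true_loop_kb, true_stall (bool).
    """
    if model not in _MODELS:
        raise InvalidArgumentError(f"model must be one of {_MODELS}, got {model!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval_s
    in_stall = (t >= stall_start_s) & (t < stall_start_s + stall_duration_s)
    active = np.cumsum(np.where(in_stall, 0.0, frame_interval_s)) - frame_interval_s
    total = np.minimum(initial_loop_kb + extrusion_rate_kb_s * np.clip(active, 0, None),
                       max_loop_kb)
    if model == NONTOPOLOGICAL:
        confining_arm_kb = total / 2.0
    else:
        confining_arm_kb = np.minimum(total, encounter_loop_kb) / 2.0
    msd_true = msd_scale * (um_per_kb * confining_arm_kb) ** 2
    loop_meas = total + rng.normal(0.0, loop_noise_kb, n_frames)
    msd_meas = np.clip(msd_true * (1.0 + rng.normal(0.0, msd_noise_frac, n_frames)), 1e-6, None)
    return pd.DataFrame(
        {
            "time_s": t,
            "loop_kb": loop_meas,
            "msd_um2": msd_meas,
            "true_loop_kb": total,
            "true_stall": in_stall,
        }
    )


def label_stages(kin: ExtrusionKinematics, threshold_um: float = 2 * 0.108) -> list:
    """Assign the standard side-flow stage label to each frame.

    Stages: "No Loop" (no loop yet), "Pre Encounter" (loop growing,
    roadblock not colocalized with the stem), "Encounter" (roadblock within
    ``threshold_um`` of the stem), "Passed" (roadblock inside the loop,
    separated from the stem).
    """
    labels = []
    enc = kin.encounter_frame
    f = kin.frames
    dist = np.hypot(
        f["roadblock_x_um"] - f["stem_x_um"], f["roadblock_y_um"] - f["stem_y_um"]
    ).to_numpy()
    for i in range(len(f)):
        if f["total_loop_kb"].iloc[i] <= 0.0:
            labels.append("No Loop")
        elif enc is None or i < enc:
            labels.append("Pre Encounter")
        elif dist[i] < threshold_um:
            labels.append("Encounter")
        else:
            labels.append("Passed")
    return labels
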