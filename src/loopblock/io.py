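"""File formats, run configuration, and the simulate→quantify→discriminate pipeline.

Movies are multi-page TIFFs with ImageJ-style metadata (axes TCYX, pixel
size in the resolution tags, frame interval in ``finterval``); tabular data
are CSVs whose column names carry units; reports are JSON with a provenance
block (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__, discriminate, mechanics, quantify, synthetic
from .errors import InsufficientDataError, InvalidArgumentError, MissingMetadataError

__all__ = [
    "read_movie",
    "write_movie",
    "RunConfig",
    "run_analysis",
    "run_pipeline",
    "config_hash",
]

log = logging.getLogger("loopblock")


def write_movie(stack: synthetic.MovieStack, path) -> None:
    """Write a two-channel stack as an ImageJ-compatible TIFF (axes TCYX)."""
    path = Path(path)
    data = np.stack([stack.dna, stack.roadblock], axis=1).astype(np.float32)
    px = stack.optics.pixel_size_um
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / px, 1.0 / px),
        metadata={
            "axes": "TCYX",
            "unit": "um",
            "finterval": stack.frame_interval_s,
        },
    )


def read_movie(
    path,
    optics: synthetic.OpticsConfig | None = None,
    frame_interval_s: float | None = None,
) -> synthetic.MovieStack:
    """Read a two-channel TCYX TIFF written by :func:`write_movie`.

    Pixel size and frame interval are taken from the file's ImageJ metadata;
    ``optics``/``frame_interval_s`` override or supply them when missing
    (a file without calibration and without overrides raises
    :class:`MissingMetadataError`). Rendering-only optics fields (PSF,
    photon yield) fall back to defaults when no override is given.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta = tif.imagej_metadata or {}
            page = tif.pages[0]
            res = page.tags.get("XResolution")
    except Exception as exc:  # noqa: BLE001 - reported with the offending path
        raise IOError(f"cannot read movie {path}: {exc}") from exc
    if axes not in ("TCYX", "CTYX") or data.ndim != 4:
        raise IOError(f"movie {path}: expected a two-channel TCYX stack, got axes {axes!r}")
    if axes == "CTYX":
        data = np.moveaxis(data, 0, 1)
    if data.shape[1] != 2:
        raise IOError(f"movie {path}: expected 2 channels, got {data.shape[1]}")

    pixel = None
    if res is not None:
        num, den = res.value
        if num:
            pixel = den / num
    interval = meta.get("finterval", None)
    if optics is None:
        if pixel is None:
            raise MissingMetadataError(
                f"movie {path} lacks pixel-size metadata and no optics override was given"
            )
        optics = synthetic.OpticsConfig(
            pixel_size_um=float(pixel), image_shape=tuple(data.shape[2:])
        )
    if frame_interval_s is None:
        if interval is None:
            raise MissingMetadataError(
                f"movie {path} lacks a frame interval and no override was given"
            )
        frame_interval_s = float(interval)
    return synthetic.MovieStack(
        dna=np.ascontiguousarray(data[:, 0]).astype(np.float32),
        roadblock=np.ascontiguousarray(data[:, 1]).astype(np.float32),
        optics=optics,
        frame_interval_s=frame_interval_s,
    )


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, JSON-serializable.

    ``mode`` is "simulate" (generate a synthetic event, default) or
    "analyze" (read an existing movie + localization table from ``paths``).
    Analysis thresholds override the prediction-test defaults.
    """

    sim: synthetic.SimulationConfig = None
    optics: synthetic.OpticsConfig = field(default_factory=synthetic.OpticsConfig)
    physical: mechanics.PhysicalParams = field(default_factory=mechanics.PhysicalParams)
    mode: str = "simulate"
    seed: int = 0
    paths: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    write_movie: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise InvalidArgumentError("mode must be 'simulate' or 'analyze'")
        if self.mode == "simulate" and self.sim is None:
            raise InvalidArgumentError("simulate mode requires a sim config")
        if self.mode == "analyze":
            movie = self.paths.get("movie")
            if not movie or not Path(movie).exists():
                raise InvalidArgumentError("analyze mode requires an existing paths['movie']")

    def to_dict(self) -> dict:
        return {
            "sim": asdict(self.sim) if self.sim is not None else None,
            "optics": asdict(self.optics),
            "physical": asdict(self.physical),
            "mode": self.mode,
            "seed": self.seed,
            "paths": dict(self.paths),
            "thresholds": dict(self.thresholds),
            "write_movie": self.write_movie,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = d.get("sim")
        if sim is not None:
            sim = dict(sim)
            if isinstance(sim.get("stall_intervals"), list):
                sim["stall_intervals"] = tuple(tuple(iv) for iv in sim["stall_intervals"])
            sim = synthetic.SimulationConfig(**sim)
        optics = d.get("optics", {})
        if isinstance(optics, dict):
            optics = dict(optics)
            if isinstance(optics.get("image_shape"), list):
                optics["image_shape"] = tuple(optics["image_shape"])
            optics = synthetic.OpticsConfig(**optics)
        physical = d.get("physical", {})
        if isinstance(physical, dict):
            physical = mechanics.PhysicalParams(**physical)
        return cls(
            sim=sim,
            optics=optics,
            physical=physical,
            mode=d.get("mode", "simulate"),
            seed=int(d.get("seed", 0)),
            paths=dict(d.get("paths", {})),
            thresholds=dict(d.get("thresholds", {})),
            write_movie=bool(d.get("write_movie", True)),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _profile_levels(stack, kin, frame, optics):
    """Tether level and loop-region profile for one frame.

    The contour polyline runs anchor-1 → stem → past the loop tip; the
    tether (1x) level is the median over the interior of the anchor-1 arm
    and the loop region is everything beyond the stem (plus a PSF margin).
    """
    a1 = np.asarray(kin.geometry["anchor1_um"])
    stem = np.asarray(kin.geometry["stem_um"])
    cfg = kin.config
    tip_len = kin.geometry["um_per_kb"] * (cfg.encounter_loop_kb + cfg.post_encounter_kb) / 2.0
    tip = stem + np.array([0.0, tip_len + 0.4])
    px = optics.pixel_size_um
    poly = np.array([a1, stem, tip]) / px
    prof = quantify.extract_profile(
        stack.dna[frame], poly, width_px=11, pixel_size_um=px, frame_index=frame
    )
    arm_len = float(np.hypot(*(stem - a1)))
    on_arm = (prof.arc_position_um > 0.25 * arm_len) & (prof.arc_position_um < 0.65 * arm_len)
    tether_level = float(np.median(prof.intensity[on_arm]))
    # skip ~2 px below the stem where the converging tether arms inflate the profile
    in_loop = prof.arc_position_um > arm_len + 2.0 * px
    loop_prof = quantify.IntensityProfile(
        arc_position_um=prof.arc_position_um[in_loop],
        intensity=prof.intensity[in_loop],
        frame_index=frame,
    )
    return tether_level, loop_prof


def run_analysis(
    sim: synthetic.SimulationConfig,
    optics: synthetic.OpticsConfig | None = None,
    physical: mechanics.PhysicalParams | None = None,
    seed: int | None = None,
    thresholds: dict | None = None,
):
    """Simulate one encounter event and run all three prediction tests on it.

    Returns ``(report, artifacts)``: the report dictionary (per-prediction
    statistics, outcomes, aggregate model call) and the intermediate
    artifacts (kinematics, movie, roadblock track, measurement series,
    stall-event table) for inspection or saving.
    """
    optics = optics or synthetic.OpticsConfig()
    physical = physical or mechanics.PhysicalParams()
    thresholds = thresholds or {}
    seed = sim.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_render, s_track, s_stall = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]

    kin = synthetic.simulate_kinematics(sim, optics, physical)
    stack = synthetic.render_movie(kin, optics, seed=s_render)
    track = synthetic.roadblock_track(
        kin, localization_noise_px=thresholds.get("localization_noise_px", 0.5),
        pixel_size_um=optics.pixel_size_um, seed=s_track,
    )
    stem_truth = kin.frames[["stem_x_um", "stem_y_um"]].to_numpy()
    series = quantify.measure_loop_series(
        stack,
        genome_kb=sim.genome_kb,
        stem_xy_um=stem_truth,
        roadblock_xy_um=track[["x_um", "y_um"]].to_numpy(),
    )

    encounter = discriminate.detect_encounter(
        series["roadblock_distance_um"].to_numpy(),
        threshold_um=thresholds.get("encounter_threshold_um",
                                    discriminate.DEFAULT_RESIDENCE_THRESHOLD_UM),
    )
    if encounter is None:
        encounter = kin.encounter_frame

    verdicts = []
    # P1: intensity multiplicity, pre-encounter loop as the I_2x reference
    try:
        if encounter is None or encounter < 4:
            raise InsufficientDataError("no usable pre-encounter reference frame")
        pre_frame = max(encounter - 3, 0)
        post_frame = len(kin) - 1
        tether_pre, loop_pre = _profile_levels(stack, kin, pre_frame, optics)
        tether_post, loop_post = _profile_levels(stack, kin, post_frame, optics)
        single_level = float(
            pd.Series(loop_pre.intensity).rolling(3, center=True, min_periods=1).mean().max()
        )
        verdicts.append(
            discriminate.classify_loop_multiplicity(
                loop_post,
                single_loop_level=single_level,
                tether_level=tether_post,
                ratio_threshold=thresholds.get("p1_ratio_threshold", 3.0),
            )
        )
    except (InsufficientDataError, InvalidArgumentError) as exc:
        verdicts.append(
            discriminate.PredictionVerdict("P1", discriminate.INCONCLUSIVE, {"error": str(exc)})
        )
    # P2: stem residence vs departure
    try:
        if encounter is None:
            raise InsufficientDataError("encounter not detected")
        verdicts.append(
            discriminate.test_stem_residence(
                series,
                encounter,
                residence_threshold_um=thresholds.get(
                    "residence_threshold_um", discriminate.DEFAULT_RESIDENCE_THRESHOLD_UM
                ),
            )
        )
    except InsufficientDataError as exc:
        verdicts.append(
            discriminate.PredictionVerdict("P2", discriminate.INCONCLUSIVE, {"error": str(exc)})
        )
    # P3: stall events recorded without side flow for the same molecule/model
    stall = synthetic.simulate_stall_event(model=sim.model, seed=s_stall)
    verdicts.append(
        discriminate.test_msd_loop_coupling(
            stall[["time_s", "loop_kb"]],
            stall[["time_s", "msd_um2"]],
            plateau_tol=thresholds.get("p3_plateau_tol", 0.2),
            min_duration_s=thresholds.get("p3_min_duration_s", 10.0),
        )
    )

    agg = discriminate.aggregate_verdict(verdicts)
    report = {
        "model_truth": sim.model,
        "aggregate_call": agg.call,
        "n_pseudo": agg.n_pseudo,
        "n_nontopo": agg.n_nontopo,
        "n_inconclusive": agg.n_inconclusive,
        "encounter_frame": None if encounter is None else int(encounter),
        "predictions": [
            {"prediction_id": v.prediction_id, "outcome": v.outcome,
             "statistics": _jsonable(v.statistics)}
            for v in verdicts
        ],
    }
    artifacts = {
        "kinematics": kin,
        "stack": stack,
        "track": track,
        "series": series,
        "stall": stall,
    }
    return report, artifacts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured pipeline and write CSV/JSON outputs.

    Writes kinematics.csv, series.csv, stall.csv, report.json, summary.txt
    and (optionally) movie.tif under ``out_dir``. Every output carries the
    config hash and seed in the report's provenance block; identical configs
    produce byte-identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())

    if config.mode == "simulate":
        report, artifacts = run_analysis(
            config.sim, config.optics, config.physical,
            seed=config.seed, thresholds=config.thresholds,
        )
        artifacts["kinematics"].frames.to_csv(out / "kinematics.csv", index=False)
        artifacts["series"].to_csv(out / "series.csv", index=False)
        artifacts["track"].to_csv(out / "roadblock_track.csv", index=False)
        artifacts["stall"].to_csv(out / "stall.csv", index=False)
        if config.write_movie:
            write_movie(artifacts["stack"], out / "movie.tif")
    else:
        stack = read_movie(config.paths["movie"], optics=config.optics,
                           frame_interval_s=config.thresholds.get("frame_interval_s"))
        track = pd.read_csv(config.paths["tracks"]) if config.paths.get("tracks") else None
        stem = (
            pd.read_csv(config.paths["stem"])[["stem_x_um", "stem_y_um"]].to_numpy()
            if config.paths.get("stem")
            else None
        )
        series = quantify.measure_loop_series(
            stack,
            stem_xy_um=stem,
            roadblock_xy_um=(track[["x_um", "y_um"]].to_numpy() if track is not None else None),
        )
        series.to_csv(out / "series.csv", index=False)
        encounter = discriminate.detect_encounter(series["roadblock_distance_um"].to_numpy())
        verdicts = []
        if encounter is not None:
            try:
                verdicts.append(discriminate.test_stem_residence(series, encounter))
            except InsufficientDataError:
                pass
        agg = (
            discriminate.aggregate_verdict(verdicts)
            if verdicts
            else discriminate.AggregateVerdict(discriminate.INCONCLUSIVE, 0, 0, 0, [])
        )
        report = {
            "aggregate_call": agg.call,
            "encounter_frame": None if encounter is None else int(encounter),
            "predictions": [
                {"prediction_id": v.prediction_id, "outcome": v.outcome,
                 "statistics": _jsonable(v.statistics)}
                for v in verdicts
            ],
        }

    report["provenance"] = {
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    lines = [
        f"loopblock {__version__} run {report['provenance']['config_hash']}"
        f" (seed {report['provenance']['seed']})",
        f"aggregate model call: {report.get('aggregate_call', 'n/a')}",
    ]
    for p in report.get("predictions", []):
        lines.append(f"  {p['prediction_id']}: {p['outcome']}")
    return "\n".join(lines) + "\n"
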