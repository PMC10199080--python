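"""The three observable-level tests that separate loop-extrusion topologies.

A pseudotopological mechanism (DNA threaded through the SMC ring) makes
three predictions for a roadblock encounter that a nontopological mechanism
does not:

* **P1 — two loops.** The blocked merge leaves a second loop co-extended
  with the first, so the side-flow intensity profile should reach ~4x the
  single-tether level (I_4x) instead of the ~2x of one loop (I_2x).
* **P2 — stem residence.** The roadblock stays pinned at the loop stem
  while the second loop grows; nontopologically it instead departs into the
  loop at the loop-extrusion speed.
* **P3 — loop growth during MSD plateaus.** Without flow, a pinned
  roadblock's MSD can stay constant while the measured loop keeps growing;
  nontopologically loop size and MSD rise and stall together.

Each test returns a :class:`PredictionVerdict` whose outcome is a pure
function of its reported statistics (re-applying the decision rule to the
statistics reproduces the outcome), and :func:`aggregate_verdict` combines
them into a per-event model call by majority over conclusive tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import mechanics
from .errors import InsufficientDataError, InvalidArgumentError
from .quantify import IntensityProfile

__all__ = [
    "SUPPORTS_PSEUDO",
    "SUPPORTS_NONTOPO",
    "INCONCLUSIVE",
    "PredictionVerdict",
    "AggregateVerdict",
    "p1_outcome",
    "p2_outcome",
    "p3_outcome",
    "classify_loop_multiplicity",
    "test_stem_residence",
    "test_msd_loop_coupling",
    "detect_encounter",
    "aggregate_verdict",
]

SUPPORTS_PSEUDO = "supports_pseudotopological"
SUPPORTS_NONTOPO = "supports_nontopological"
INCONCLUSIVE = "inconclusive"

#: 2 px at the default 0.108 µm/px calibration.
DEFAULT_RESIDENCE_THRESHOLD_UM = 2 * 0.108


@dataclass
class PredictionVerdict:
    """Outcome of one prediction test plus the statistics that justify it."""

    prediction_id: str
    outcome: str
    statistics: dict = field(default_factory=dict)


@dataclass
class AggregateVerdict:
    """Majority model call over the conclusive prediction tests."""

    call: str
    n_pseudo: int
    n_nontopo: int
    n_inconclusive: int
    verdicts: list

    def table(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            row = {"prediction_id": v.prediction_id, "outcome": v.outcome}
            row.update(v.statistics)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pure decision rules (outcome = rule(statistics)); kept separate so verdicts
# are auditable from their reported statistics alone.

def p1_outcome(
    peak_ratio: float,
    snr: float,
    ratio_threshold: float = 3.0,
    min_visible_ratio: float = 1.5,
    snr_min: float = 3.0,
) -> str:
    if not np.isfinite(peak_ratio) or snr < snr_min or peak_ratio < min_visible_ratio:
        return INCONCLUSIVE
    return SUPPORTS_PSEUDO if peak_ratio >= ratio_threshold else SUPPORTS_NONTOPO


def p2_outcome(
    frac_below_threshold: float,
    speed_ratio: float,
    monotonicity: float,
    residence_threshold_um: float = DEFAULT_RESIDENCE_THRESHOLD_UM,
    speed_band: tuple = (0.5, 2.0),
    min_monotonicity: float = 0.7,
    min_residence_frac: float = 0.9,
) -> str:
    if frac_below_threshold >= min_residence_frac:
        return SUPPORTS_PSEUDO
    if (
        np.isfinite(speed_ratio)
        and speed_band[0] <= speed_ratio <= speed_band[1]
        and monotonicity >= min_monotonicity
    ):
        return SUPPORTS_NONTOPO
    return INCONCLUSIVE


def p3_outcome(n_stalls: int, n_stalls_with_loop_growth: int) -> str:
    if n_stalls == 0:
        return INCONCLUSIVE
    return SUPPORTS_PSEUDO if n_stalls_with_loop_growth > 0 else SUPPORTS_NONTOPO


# ---------------------------------------------------------------------------
# P1: loop multiplicity from intensity profiles

def classify_loop_multiplicity(
    post_profile: IntensityProfile,
    single_loop_level: float,
    tether_level: float,
    ratio_threshold: float = 3.0,
    min_visible_ratio: float = 1.5,
    snr_min: float = 3.0,
) -> PredictionVerdict:
    """Single vs double loop from a post-encounter intensity profile.

    ``tether_level`` is the single-strand (1x) profile level and
    ``single_loop_level`` the pre-encounter loop level (~2x, checked within
    25%). The profile peak (3-point smoothed) is compared to the midpoint
    between I_2x and I_4x: a peak ratio >= ``ratio_threshold`` (default 3)
    supports the double-loop (pseudotopological) reading. Profiles with no
    visible loop or with SNR below ``snr_min`` are inconclusive.
    """
    if not np.isfinite(tether_level) or tether_level <= 0:
        raise InsufficientDataError("tether baseline level missing or non-positive")
    if abs(single_loop_level / (2.0 * tether_level) - 1.0) > 0.25:
        raise InvalidArgumentError(
            "single_loop_level is not ~2x the tether level; check the baselines"
        )
    intensity = post_profile.intensity
    if len(intensity) < 3:
        raise InsufficientDataError("profile too short")
    smooth = pd.Series(intensity).rolling(3, center=True, min_periods=1).mean().to_numpy()
    peak_ratio = float(smooth.max() / tether_level)
    resid = intensity - smooth
    sigma = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    snr = float(tether_level / sigma) if sigma > 0 else float("inf")
    stats = {
        "peak_ratio": peak_ratio,
        "snr": snr,
        "tether_level": float(tether_level),
        "single_loop_level": float(single_loop_level),
    }
    return PredictionVerdict(
        "P1",
        p1_outcome(peak_ratio, snr, ratio_threshold, min_visible_ratio, snr_min),
        stats,
    )


# ---------------------------------------------------------------------------
# P2: stem residence vs departure at the extrusion speed

def test_stem_residence(
    series: pd.DataFrame,
    encounter_frame: int,
    rate_kb_s: float | None = None,
    residence_threshold_um: float = DEFAULT_RESIDENCE_THRESHOLD_UM,
    speed_band: tuple = (0.5, 2.0),
    min_monotonicity: float = 0.7,
    min_points: int = 5,
) -> PredictionVerdict:
    """Does the roadblock stay at the stem or depart at the extrusion speed?

    ``series`` is a per-frame measurement table (columns time_s, loop_kb,
    loop_length_um, roadblock_distance_um). The departure speed is the
    linear-fit slope of distance vs time after ``encounter_frame``; the
    extrusion speed is the loop-growth rate (fit from loop_kb unless given)
    converted to µm/s through the measured arm extension per kb. A roadblock
    that stays within ``residence_threshold_um`` of the stem (default 2 px,
    in >= 90% of frames so single-frame localization outliers do not flip
    the call) supports the pseudotopological model; monotone departure at a
    speed within ``speed_band`` of the extrusion speed supports the
    nontopological one.
    """
    post = series.iloc[int(encounter_frame):]
    post = post[np.isfinite(post["roadblock_distance_um"])]
    if len(post) < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} post-encounter frames with a valid distance"
        )
    t = post["time_s"].to_numpy()
    d = post["roadblock_distance_um"].to_numpy()
    loop = post["loop_kb"].to_numpy()
    max_distance = float(np.max(d))
    frac_below = float(np.mean(d < residence_threshold_um))
    final_distance = float(np.median(d[-3:]))

    # fit departure and extrusion rate only while the loop is still growing —
    # after extrusion stops (DNA exhausted / loop disrupted) nothing moves
    final_level = float(np.nanmedian(loop[-3:]))
    active = np.isfinite(loop) & (loop < final_level - 0.5)
    if active.sum() < min_points:
        active = np.ones(len(post), dtype=bool)
    fit = sps.linregress(t[active], d[active])
    departure_speed = float(fit.slope)

    if rate_kb_s is None:
        ok = active & np.isfinite(loop)
        rate_kb_s = float(sps.linregress(t[ok], loop[ok]).slope)

    # measured arm extension per kb (loop length / arm size) at the event end
    tail = post.tail(5)
    arm_kb = float(np.nanmedian(tail["loop_kb"])) / 2.0
    length_um = float(np.nanmedian(tail["loop_length_um"]))
    if arm_kb > 0 and np.isfinite(length_um):
        extrusion_speed = mechanics.genomic_to_spatial_speed(
            max(rate_kb_s, 0.0), length_um / arm_kb
        )
    else:
        extrusion_speed = float("nan")
    speed_ratio = (
        departure_speed / extrusion_speed if extrusion_speed and extrusion_speed > 0 else float("nan")
    )
    if np.ptp(d) > 0:
        monotonicity = float(sps.spearmanr(t, d).statistic)
    else:
        monotonicity = 0.0

    enc_loop = float(series["loop_kb"].iloc[int(encounter_frame)])
    added_kb = max(float(np.nanmedian(tail["loop_kb"])) - enc_loop, 0.0)
    if arm_kb > 0 and np.isfinite(length_um):
        expected_final = mechanics.expected_roadblock_position(
            min(added_kb, arm_kb), arm_kb, length_um
        )
    else:
        expected_final = float("nan")

    stats = {
        "departure_speed_um_s": departure_speed,
        "extrusion_speed_um_s": float(extrusion_speed),
        "speed_ratio": float(speed_ratio),
        "max_distance_um": max_distance,
        "frac_below_threshold": frac_below,
        "final_distance_um": final_distance,
        "expected_final_distance_um": float(expected_final),
        "monotonicity": monotonicity,
        "n_post_frames": int(len(post)),
        "rate_kb_s": float(rate_kb_s),
    }
    return PredictionVerdict(
        "P2",
        p2_outcome(
            frac_below, speed_ratio, monotonicity,
            residence_threshold_um, speed_band, min_monotonicity,
        ),
        stats,
    )


# ---------------------------------------------------------------------------
# P3: loop growth inside MSD plateaus

def _plateau_windows(
    msd: np.ndarray, dt: float, plateau_tol: float, min_duration_s: float, smooth_points: int
) -> list:
    """Contiguous index ranges where the smoothed MSD is flat for >= min_duration."""
    sm = pd.Series(msd).rolling(smooth_points, center=True, min_periods=1).mean().to_numpy()
    w = max(int(round(min_duration_s / dt)) + 1, 2)
    n = len(sm)
    flat = np.zeros(n, dtype=bool)
    for i in range(0, n - w + 1):
        seg = sm[i : i + w]
        m = seg.mean()
        if m > 0 and (seg.max() - seg.min()) / m < plateau_tol:
            flat[i : i + w] = True
    windows = []
    i = 0
    while i < n:
        if flat[i]:
            j = i
            while j < n and flat[j]:
                j += 1
            if j - i >= w:
                windows.append((i, j))
            i = j
        else:
            i += 1
    return windows


def test_msd_loop_coupling(
    loop_series: pd.DataFrame,
    msd_series: pd.DataFrame,
    plateau_tol: float = 0.2,
    min_duration_s: float = 10.0,
    alpha: float = 0.05,
    min_growth_kb: float = 1.5,
    smooth_points: int = 5,
) -> PredictionVerdict:
    """Does the loop ever grow while the roadblock's MSD stays constant?

    Stall windows are intervals where the (rolling-mean) windowed MSD varies
    by less than ``plateau_tol`` (relative) for at least ``min_duration_s``.
    Within each window — edge-trimmed by the smoothing half-width, since
    plateau boundaries are only resolved to that scale — the loop-size
    series is tested for growth with a one-sided slope test at level
    ``alpha``; to count, the fitted growth over the window must also reach
    ``min_growth_kb`` so that sub-resolution slopes in a noisy but flat
    series are not scored. Any stall with significant growth supports the
    pseudotopological model; stalls with none support the nontopological
    one.
    """
    for df, col in ((loop_series, "loop_kb"), (msd_series, "msd_um2")):
        if "time_s" not in df.columns or col not in df.columns:
            raise InvalidArgumentError(f"series needs columns time_s and {col}")
    t_loop = loop_series["time_s"].to_numpy(dtype=float)
    t_msd = msd_series["time_s"].to_numpy(dtype=float)
    if len(t_loop) != len(t_msd) or not np.allclose(t_loop, t_msd):
        raise InvalidArgumentError("loop and MSD series must share the same time base")
    if len(t_loop) < 3:
        raise InsufficientDataError("series too short")
    dt = float(np.median(np.diff(t_loop)))

    windows = _plateau_windows(
        msd_series["msd_um2"].to_numpy(dtype=float), dt, plateau_tol, min_duration_s, smooth_points
    )
    loop = loop_series["loop_kb"].to_numpy(dtype=float)
    n_growth = 0
    max_growth = 0.0
    details = []
    trim = smooth_points
    for i, j in windows:
        i2, j2 = i + trim, j - trim
        if j2 - i2 < 3:
            i2, j2 = i, j
        fit = sps.linregress(t_loop[i2:j2], loop[i2:j2])
        growth_kb = float(fit.slope * (t_loop[j2 - 1] - t_loop[i2]))
        p_one = fit.pvalue / 2.0 if fit.slope > 0 else 1.0 - fit.pvalue / 2.0
        significant = fit.slope > 0 and p_one < alpha and growth_kb >= min_growth_kb
        n_growth += int(significant)
        max_growth = max(max_growth, growth_kb)
        details.append((float(t_loop[i]), float(t_loop[j - 1]), growth_kb, float(p_one)))

    stats = {
        "n_stalls": len(windows),
        "n_stalls_with_loop_growth": n_growth,
        "max_growth_kb": max_growth,
        "stall_windows": details,
    }
    return PredictionVerdict("P3", p3_outcome(len(windows), n_growth), stats)


def detect_encounter(
    distance_um: np.ndarray,
    threshold_um: float = DEFAULT_RESIDENCE_THRESHOLD_UM,
    min_frames: int = 2,
) -> int | None:
    """First frame where the roadblock-stem distance stays below threshold.

    Operational encounter definition: colocalization within ``threshold_um``
    (default 2 px) for at least ``min_frames`` consecutive frames.
    """
    d = np.asarray(distance_um, dtype=float)
    below = np.isfinite(d) & (d < threshold_um)
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= min_frames:
            return i - min_frames + 1
    return None


def aggregate_verdict(verdicts: list) -> AggregateVerdict:
    """Majority model call over conclusive prediction verdicts (ties inconclusive)."""
    if not verdicts:
        raise InvalidArgumentError("need at least one verdict")
    n_p = sum(v.outcome == SUPPORTS_PSEUDO for v in verdicts)
    n_n = sum(v.outcome == SUPPORTS_NONTOPO for v in verdicts)
    n_i = sum(v.outcome == INCONCLUSIVE for v in verdicts)
    if n_p > n_n:
        call = "pseudotopological"
    elif n_n > n_p:
        call = "nontopological"
    else:
        call = INCONCLUSIVE
    return AggregateVerdict(call=call, n_pseudo=n_p, n_nontopo=n_n, n_inconclusive=n_i,
                            verdicts=list(verdicts))
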