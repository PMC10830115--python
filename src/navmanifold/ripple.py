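"""Sharp-wave-ripple detection and ripple-associated manifold geometry.

Detection: zero-phase band-pass 140-230 Hz (3rd-order Butterworth applied
forward-backward), squared signal, 11-sample moving average, z-score.
Candidate events are periods with normalized power > 3; candidates within
30 ms of each other are merged, events with peak power < 7 or duration
outside [15, 300] ms are discarded, and the event peak time is the
negative peak of the band-passed trace.

Geometry: 76.8-ms bins centered on 100 randomly sampled ripple peaks are
embedded jointly with the awake 512-ms bins (z-scored coordinates), then
summarized by (i) the mean first-3-nearest-neighbor distance from ripple
points to the awake cloud, (ii) dispersion (mean pairwise distance among
ripple points), (iii) the concentration factor

    K = Rbar (p - Rbar^2) / (1 - Rbar^2),   p = 3,

where Rbar is the mean resultant length of unit vectors from the awake
cloud's center of mass to each ripple point, plus pairwise-correlation
shifts between states, nearest-segment association against 20 path
segments per turn direction, and peri-ripple trajectory metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt
from scipy.spatial.distance import cdist, pdist

from .embed import Embedding, joint_embed
from .maze import landmark_of_u
from .session import BehaviorSeries, BinnedActivity, SpikeTable, TransformLedger

RIPPLE_BAND_HZ = (140.0, 230.0)
POWER_WINDOW_SAMPLES = 11
CANDIDATE_Z = 3.0
PEAK_Z_MIN = 7.0
MERGE_GAP_S = 0.030
DURATION_S = (0.015, 0.300)
EVENT_BIN_S = 0.0768
MIN_RIPPLES_PER_SESSION = 100


@dataclass
class RippleEvents:
    events: pd.DataFrame  # start_s, peak_s, end_s, peak_z, dur_ms
    usable: bool = True   # False when a session yields <= 100 events

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peaks(self) -> np.ndarray:
        return self.events["peak_s"].to_numpy()


@dataclass
class RippleGeometry:
    first3nn: float
    dispersion: float
    rbar: float
    k: float | None       # None when Rbar is degenerate (= 1)
    n_ripple_points: int


def detect_ripples(lfp: np.ndarray, fs: float) -> RippleEvents:
    """Detect ripple events in an LFP trace; see module docstring for rules."""
    lfp = np.asarray(lfp, dtype=float)
    if fs <= 2 * RIPPLE_BAND_HZ[1]:
        raise ValueError("sampling rate too low for the 140-230 Hz band")
    if not np.all(np.isfinite(lfp)):
        raise ValueError("non-finite LFP samples")
    if np.std(lfp) == 0:
        raise ValueError("constant LFP")

    b, a = butter(3, [f / (fs / 2) for f in RIPPLE_BAND_HZ], btype="bandpass")
    filtered = filtfilt(b, a, lfp)
    power = uniform_filter1d(filtered**2, POWER_WINDOW_SAMPLES)
    z = (power - power.mean()) / power.std()
    events = events_from_normalized_power(z, filtered, fs)
    return RippleEvents(events=events, usable=len(events) > MIN_RIPPLES_PER_SESSION)


def events_from_normalized_power(z: np.ndarray, filtered: np.ndarray, fs: float) -> pd.DataFrame:
    """Candidate -> event rules on a normalized ripple-power series.

    Candidates are contiguous runs with z > 3; candidates separated by less
    than 30 ms merge; merged events are kept only with peak z >= 7 and
    duration within [15, 300] ms; the event peak time is the negative peak
    of the band-passed trace within the event.
    """
    above = z > CANDIDATE_Z
    if not np.any(above):
        return _empty_events()
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(z)]])

    gap = int(round(MERGE_GAP_S * fs))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    rows = []
    for s, e in merged:
        dur = (e - s) / fs
        peak_z = float(z[s:e].max())
        if peak_z < PEAK_Z_MIN or not DURATION_S[0] <= dur <= DURATION_S[1]:
            continue
        peak_i = s + int(np.argmin(filtered[s:e]))
        rows.append((s / fs, peak_i / fs, e / fs, peak_z, dur * 1000.0))
    return (pd.DataFrame(rows, columns=["start_s", "peak_s", "end_s", "peak_z", "dur_ms"])
            if rows else _empty_events())


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=["start_s", "peak_s", "end_s", "peak_z", "dur_ms"])


# ---------------------------------------------------------------------------
# event binning


def _bins_at(spike_table: SpikeTable, centers: np.ndarray, width: float,
             sqrt: bool = True) -> BinnedActivity:
    ids = spike_table.unit_ids
    rates = np.zeros((len(centers), len(ids)))
    for j, uid in enumerate(ids):
        ts = spike_table.times_of(uid)
        for i, c in enumerate(centers):
            rates[i, j] = np.sum((ts >= c - width / 2) & (ts < c + width / 2)) / width
    if sqrt:
        rates = np.sqrt(rates)
    edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
    return BinnedActivity(edges=edges, rates=rates, unit_ids=np.asarray(list(ids)),
                          ledger=TransformLedger(sqrt=sqrt))


def ripple_bins(
    spike_table: SpikeTable,
    events: RippleEvents,
    n_events: int = 100,
    width: float = EVENT_BIN_S,
    seed: int = 0,
) -> tuple[BinnedActivity, np.ndarray]:
    """One sqrt-rate bin per sampled event, centered on its peak.

    Returns (activity, sampled peak times).
    """
    peaks = events.peaks
    if len(peaks) < n_events:
        raise ValueError(f"only {len(peaks)} events; need {n_events}")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(peaks), size=n_events, replace=False))
    centers = peaks[chosen]
    return _bins_at(spike_table, centers, width), centers


# ---------------------------------------------------------------------------
# geometry metrics


def first3nn_distance(ripple_pts: np.ndarray, awake_pts: np.ndarray) -> float:
    d = cdist(ripple_pts, awake_pts)
    d.sort(axis=1)
    return float(d[:, :3].mean())


def concentration_factor(ripple_pts: np.ndarray, awake_center: np.ndarray,
                         p: int = 3) -> tuple[float, float | None]:
    """(Rbar, K): resultant length and concentration of ripple directions."""
    vec = ripple_pts - awake_center
    norm = np.linalg.norm(vec, axis=1)
    unit = vec[norm > 0] / norm[norm > 0, None]
    rbar = float(np.linalg.norm(unit.mean(axis=0)))
    if rbar >= 1.0 - 1e-12:
        warnings.warn("degenerate ripple directions (Rbar = 1); K undefined", stacklevel=2)
        return rbar, None
    return rbar, float(rbar * (p - rbar**2) / (1 - rbar**2))


def ripple_geometry(joint: Embedding) -> RippleGeometry:
    """Summarize ripple-point geometry of a joint (z-scored) embedding."""
    awake, ripple = joint.awake_coords, joint.event_coords
    if len(awake) < 3:
        raise ValueError("need >= 3 awake points")
    if len(ripple) < 2:
        raise ValueError("need >= 2 ripple points")
    rbar, k = concentration_factor(ripple, awake.mean(axis=0), p=joint.d)
    return RippleGeometry(
        first3nn=first3nn_distance(ripple, awake),
        dispersion=float(pdist(ripple).mean()),
        rbar=rbar, k=k, n_ripple_points=len(ripple),
    )


def correlation_shift(awake: BinnedActivity, ripple: BinnedActivity):
    """|r_awake - r_ripple| per unit pair; returns (matrix, mean).

    Units with no spikes in either state (or zero variance) are excluded.
    """
    if list(awake.unit_ids) != list(ripple.unit_ids):
        raise ValueError("unit sets differ between states")
    ok = (
        (awake.rates.sum(axis=0) > 0) & (ripple.rates.sum(axis=0) > 0)
        & (awake.rates.std(axis=0) > 0) & (ripple.rates.std(axis=0) > 0)
    )
    if ok.sum() < 2:
        raise ValueError("fewer than 2 qualifying units")
    ra = np.corrcoef(awake.rates[:, ok].T)
    rr = np.corrcoef(ripple.rates[:, ok].T)
    iu = np.triu_indices(int(ok.sum()), k=1)
    delta = np.abs(ra - rr)
    return delta, float(delta[iu].mean())


# ---------------------------------------------------------------------------
# segment association


@dataclass
class ManifoldSegments:
    centers: np.ndarray    # (m, d) segment centers of mass in embedding space
    landmark: np.ndarray   # landmark label per segment
    turn: np.ndarray       # turn direction per segment
    u_mid: np.ndarray      # linearized midpoint per segment


def build_segments(
    awake_coords: np.ndarray, behavior: BehaviorSeries, n_segments: int = 20
) -> ManifoldSegments:
    """20 equal linearized segments per turn direction with embedding centers."""
    f = behavior.frame
    u = f["u"].to_numpy()
    turn = f["turn"].to_numpy()
    centers, labels, turns, mids = [], [], [], []
    for t in ("L", "R"):
        for k in range(n_segments):
            lo, hi = k / n_segments, (k + 1) / n_segments
            sel = (turn == t) & (u >= lo) & (u < hi)
            mid = (lo + hi) / 2
            if not np.any(sel):
                warnings.warn(f"empty segment {t}{k}; excluded", stacklevel=2)
                continue
            centers.append(awake_coords[sel].mean(axis=0))
            labels.append(landmark_of_u(mid)[0])
            turns.append(t)
            mids.append(mid)
    return ManifoldSegments(
        centers=np.array(centers), landmark=np.array(labels, dtype=object),
        turn=np.array(turns, dtype=object), u_mid=np.array(mids),
    )


def nearest_segments(points: np.ndarray, segments: ManifoldSegments) -> np.ndarray:
    return np.argmin(cdist(points, segments.centers), axis=1)


LANDMARKS = ("box", "choice", "arm", "reward", "other")


def _landmark_fractions(idx: np.ndarray, segments: ManifoldSegments) -> dict:
    lab = segments.landmark[idx]
    return {name: float(np.mean(lab == name)) for name in LANDMARKS}


def segment_association(
    segments: ManifoldSegments,
    ripple_pts: np.ndarray,
    n_null: int = 1000,
    seed: int = 0,
    awake_coords: np.ndarray | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Fraction of ripple points nearest each landmark, with a scatter null.

    The null scatters the same number of points uniformly in the axis-
    aligned bounding box of the awake cloud (or of the segment centers when
    the cloud is not given), ``n_null`` times.
    """
    observed = _landmark_fractions(nearest_segments(ripple_pts, segments), segments)
    box_src = awake_coords if awake_coords is not None else segments.centers
    lo, hi = box_src.min(axis=0), box_src.max(axis=0)
    rng = np.random.default_rng(seed)
    null_rows = []
    for _ in range(n_null):
        scatter = rng.uniform(lo, hi, size=ripple_pts.shape)
        null_rows.append(_landmark_fractions(nearest_segments(scatter, segments), segments))
    return observed, pd.DataFrame(null_rows)


# ---------------------------------------------------------------------------
# peri-ripple dynamics


@dataclass
class PeriRippleResult:
    dist_pre_ripple: float
    dist_ripple_post: float
    seg_change_pre_ripple: float
    seg_change_pre_post: float
    n_repetitions: int


def peri_ripple_dynamics(
    spike_table: SpikeTable,
    events: RippleEvents,
    awake: BinnedActivity,
    behavior: BehaviorSeries,
    seed: int = 0,
    n_events: int = 30,
    n_repetitions: int = 10,
    offset_s: float = 0.2,
    width: float = EVENT_BIN_S,
    n_neighbors: int = 20,
) -> PeriRippleResult:
    """Trajectory metrics for pre/ripple/post population vectors.

    Per repetition: sample ``n_events`` ripples without replacement
    (selections are returned to the pool between repetitions), bin activity
    at peak-200 ms, peak and peak+200 ms, joint-embed with the awake bins,
    and measure Euclidean step sizes and nearest-segment index changes.
    """
    peaks = events.peaks
    if len(peaks) < n_events:
        raise ValueError(f"need >= {n_events} events")
    rng = np.random.default_rng(seed)
    out = np.zeros(4)
    for _ in range(n_repetitions):
        chosen = np.sort(rng.choice(len(peaks), size=n_events, replace=False))
        centers = peaks[chosen]
        all_centers = np.concatenate([centers - offset_s, centers, centers + offset_s])
        evt = _bins_at(spike_table, all_centers, width)
        joint = joint_embed(awake, evt, n_neighbors=n_neighbors)
        coords = joint.event_coords
        pre, rip, post = (coords[:n_events], coords[n_events:2 * n_events],
                          coords[2 * n_events:])
        segments = build_segments(joint.awake_coords, behavior)
        s_pre = segments.u_mid[nearest_segments(pre, segments)]
        s_rip = segments.u_mid[nearest_segments(rip, segments)]
        s_post = segments.u_mid[nearest_segments(post, segments)]
        out += np.array([
            np.linalg.norm(rip - pre, axis=1).mean(),
            np.linalg.norm(post - rip, axis=1).mean(),
            np.abs(s_rip - s_pre).mean() * len(segments.centers) / 2,
            np.abs(s_post - s_pre).mean() * len(segments.centers) / 2,
        ])
    out /= n_repetitions
    return PeriRippleResult(*out, n_repetitions=n_repetitions)
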