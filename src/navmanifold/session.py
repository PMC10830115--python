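"""Session I/O, unit classification, binning and behavioral series.

A session directory holds plain-text tables:

* ``spikes.tsv``   -- unit_id, t_s
* ``units.tsv``    -- unit_id, region, width_ms, rate_hz [, iso_dist, isi_idx, amp_uv]
* ``position.tsv`` -- t_s, x_cm, y_cm [, hd_rad] sampled at 39.0625 Hz
* ``trials.tsv``   -- idx, turn, correct, box_t0, box_t1 (optional; T-maze only)
* ``lfp.f32`` + ``lfp.json`` -- little-endian float32 trace with {"fs_hz": ...}

Firing rates are binned at 512 ms by default.  Manifold construction uses
the square root of the instantaneous rate to stabilize variance; transforms
are recorded in an explicit ledger (rate -> sqrt -> smooth -> z-score) so
downstream stages can assert what a matrix carries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .maze import BOX_U, REWARD_U, TMazeGeometry

POSITION_FS = 39.0625          # Hz; tracking frame rate
POSITION_DT = 1.0 / POSITION_FS
DEFAULT_BIN_S = 0.512


# ---------------------------------------------------------------------------
# containers


@dataclass
class SpikeTable:
    """Spike times per unit plus unit metadata."""

    spikes: pd.DataFrame  # columns unit_id, t_s (sorted within unit)
    units: pd.DataFrame   # unit_id, region, width_ms, rate_hz, optional quality cols

    def __post_init__(self) -> None:
        t = self.spikes["t_s"].to_numpy()
        if len(t) and t.min() < 0:
            raise ValueError("negative spike times")
        for uid, grp in self.spikes.groupby("unit_id", sort=False):
            ts = grp["t_s"].to_numpy()
            if np.any(np.diff(ts) < 0):
                raise ValueError(f"unsorted spike times for unit {uid}")

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    def times_of(self, unit_id) -> np.ndarray:
        return self.spikes.loc[self.spikes["unit_id"] == unit_id, "t_s"].to_numpy()

    def subset(self, unit_ids) -> "SpikeTable":
        unit_ids = list(unit_ids)
        return SpikeTable(
            spikes=self.spikes[self.spikes["unit_id"].isin(unit_ids)].reset_index(drop=True),
            units=self.units[self.units["unit_id"].isin(unit_ids)].reset_index(drop=True),
        )


@dataclass(frozen=True)
class TransformLedger:
    """Which transforms a binned matrix carries, in application order."""

    sqrt: bool = False
    smooth_sigma_bins: float = 0.0
    zscored: bool = False


@dataclass
class BinnedActivity:
    """T x N matrix of per-bin firing rates with its transform ledger."""

    edges: np.ndarray          # T+1 bin edges, seconds; bins are [t, t+dt)
    rates: np.ndarray          # T x N
    unit_ids: np.ndarray
    ledger: TransformLedger = field(default_factory=TransformLedger)

    @property
    def bin_s(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_bins(self) -> int:
        return self.rates.shape[0]

    @property
    def n_units(self) -> int:
        return self.rates.shape[1]


@dataclass
class BehaviorSeries:
    """Per-bin behavioral variables aligned to a BinnedActivity."""

    frame: pd.DataFrame  # t_s, x_cm, y_cm, speed_cms, u, turn, hd_rad, trial, in_box, in_reward


@dataclass
class Session:
    """In-memory session as read from disk."""

    spikes: SpikeTable
    position: pd.DataFrame
    trials: pd.DataFrame | None = None
    lfp: np.ndarray | None = None
    lfp_fs: float | None = None
    task: str = "tmaze"

    @property
    def t_end(self) -> float:
        return float(self.position["t_s"].iloc[-1] + POSITION_DT)


# ---------------------------------------------------------------------------
# reading and writing


def write_session(out_dir, session: Session, truth: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.spikes.spikes.to_csv(out / "spikes.tsv", sep="\t", index=False)
    session.spikes.units.to_csv(out / "units.tsv", sep="\t", index=False)
    session.position.to_csv(out / "position.tsv", sep="\t", index=False)
    trials = session.trials if session.trials is not None else pd.DataFrame(
        columns=["idx", "turn", "correct", "box_t0", "box_t1"]
    )
    trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    if session.lfp is not None:
        session.lfp.astype("<f4").tofile(out / "lfp.f32")
        (out / "lfp.json").write_text(json.dumps({"fs_hz": session.lfp_fs, "channel": 0}))
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, default=_jsonify))
    return out


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_session(session_dir, task: str = "tmaze") -> Session:
    d = Path(session_dir)
    for name in ("spikes.tsv", "units.tsv", "position.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing required file {name} in {d}")
    spikes = pd.read_csv(d / "spikes.tsv", sep="\t")
    units = pd.read_csv(d / "units.tsv", sep="\t")
    position = pd.read_csv(d / "position.tsv", sep="\t")
    st = SpikeTable(spikes=spikes, units=units)

    dt = np.diff(position["t_s"].to_numpy())
    if len(dt):
        if not np.allclose(dt.mean(), POSITION_DT, rtol=1e-3):
            raise ValueError("position timestamps are not at 39.0625 Hz")
        if np.any(dt > 1.0):
            warnings.warn("position timestamp gaps > 1 s", stacklevel=2)

    trials = None
    if (d / "trials.tsv").exists():
        trials = pd.read_csv(d / "trials.tsv", sep="\t")
        if trials.empty:
            trials = None
    lfp = lfp_fs = None
    if (d / "lfp.f32").exists():
        lfp = np.fromfile(d / "lfp.f32", dtype="<f4").astype(float)
        lfp_fs = float(json.loads((d / "lfp.json").read_text())["fs_hz"])
    return Session(spikes=st, position=position, trials=trials, lfp=lfp, lfp_fs=lfp_fs, task=task)


# ---------------------------------------------------------------------------
# unit classification and session selection


def classify_units(units: pd.DataFrame) -> pd.Series:
    """Label units as 'CA1 principal', 'SUB principal' or 'excluded'.

    Principal neurons have spike width > 0.4 ms; CA1 principal cells must
    additionally fire below 10 Hz on average (no rate ceiling is applied in
    SUB, where principal cells can sustain high rates).  When quality
    metrics are present, units must also pass isolation distance > 20,
    ISI index < 0.2, amplitude > 50 uV and mean rate > 0.1 Hz.
    """
    labels = []
    for _, row in units.iterrows():
        width = row.get("width_ms", np.nan)
        rate = row.get("rate_hz", np.nan)
        if not np.isfinite(width):
            warnings.warn(f"unit {row['unit_id']} has no spike width; excluded", stacklevel=2)
            labels.append("excluded")
            continue
        ok = width > 0.4
        if row["region"] == "CA1":
            ok = ok and rate < 10.0
        for col, test in [
            ("iso_dist", lambda v: v > 20),
            ("isi_idx", lambda v: v < 0.2),
            ("amp_uv", lambda v: v > 50),
        ]:
            if col in row.index and np.isfinite(row[col]):
                ok = ok and bool(test(row[col]))
        if "rate_hz" in row.index and np.isfinite(rate):
            ok = ok and rate > 0.1
        labels.append(f"{row['region']} principal" if ok else "excluded")
    return pd.Series(labels, index=units.index, name="label")


def select_session(units: pd.DataFrame, region: str, min_units: int = 10) -> bool:
    """A session qualifies with >= 10 principal units above 0.1 Hz in the region."""
    labels = classify_units(units)
    mask = (labels == f"{region} principal") & (units["rate_hz"] > 0.1)
    return int(mask.sum()) >= min_units


# ---------------------------------------------------------------------------
# binning and transforms


def bin_activity(
    spike_table: SpikeTable,
    interval: tuple[float, float],
    bin_s: float = DEFAULT_BIN_S,
    sqrt: bool = True,
    smooth_sigma_bins: float = 0.0,
    zscore: bool = False,
    unit_ids=None,
) -> BinnedActivity:
    """Bin spikes into instantaneous firing rates and apply the transform ledger.

    Bins are half-open ``[t, t+bin_s)`` anchored at the interval start; the
    ledger order is fixed: rate -> sqrt -> Gaussian smoothing (reflective
    boundaries) -> per-unit z-score over the interval.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("empty interval")
    n_bins = int(np.floor((t1 - t0) / bin_s))
    if n_bins < 1:
        raise ValueError("interval shorter than one bin")
    edges = t0 + bin_s * np.arange(n_bins + 1)
    if unit_ids is None:
        unit_ids = spike_table.unit_ids
    unit_ids = np.asarray(list(unit_ids))

    rates = np.zeros((n_bins, len(unit_ids)))
    for j, uid in enumerate(unit_ids):
        ts = spike_table.times_of(uid)
        ts = ts[(ts >= t0) & (ts < edges[-1])]
        counts, _ = np.histogram(ts, bins=edges)
        rates[:, j] = counts / bin_s

    if sqrt:
        rates = np.sqrt(rates)
    if smooth_sigma_bins > 0:
        rates = gaussian_filter1d(rates, smooth_sigma_bins, axis=0, mode="reflect")
    if zscore:
        mu = rates.mean(axis=0)
        sd = rates.std(axis=0)
        zero = sd == 0
        if np.any(zero):
            warnings.warn(f"{int(zero.sum())} unit(s) with zero variance; z-rows set to 0",
                          stacklevel=2)
        sd[zero] = 1.0
        rates = (rates - mu) / sd
        rates[:, zero] = 0.0

    return BinnedActivity(
        edges=edges, rates=rates, unit_ids=unit_ids,
        ledger=TransformLedger(sqrt=sqrt, smooth_sigma_bins=smooth_sigma_bins, zscored=zscore),
    )


def circular_shift_spikes(
    spike_table: SpikeTable, interval: tuple[float, float], rng: np.random.Generator
) -> SpikeTable:
    """Independently circularly shift each unit's spike train within the interval.

    Shifts are drawn uniformly on (0, interval length); per-unit spike
    counts are preserved exactly.  Standard surrogate for chance levels and
    topology nulls.
    """
    t0, t1 = interval
    length = t1 - t0
    parts = []
    for uid in spike_table.unit_ids:
        ts = spike_table.times_of(uid)
        inside = (ts >= t0) & (ts < t1)
        shifted = np.sort((ts[inside] - t0 + rng.uniform(0, length)) % length + t0)
        keep = np.concatenate([ts[~inside], shifted])
        parts.append(pd.DataFrame({"unit_id": uid, "t_s": np.sort(keep)}))
    spikes = pd.concat(parts, ignore_index=True) if parts else spike_table.spikes.iloc[:0]
    return SpikeTable(spikes=spikes, units=spike_table.units.copy())


# ---------------------------------------------------------------------------
# behavior


def derive_behavior(
    position: pd.DataFrame,
    trials: pd.DataFrame | None,
    edges: np.ndarray,
    task: str = "tmaze",
    geometry: TMazeGeometry | None = None,
    smooth_sigma_bins: float = 1.0,
) -> BehaviorSeries:
    """Down-sample tracking to activity bins and derive speed and linearized position.

    Per-bin position takes every 20th tracking sample (20 x 25.6 ms = 512 ms),
    X and Y are Gaussian-smoothed separately (sigma = 1 bin), speed is the
    distance between adjacent smoothed positions divided by the bin width and
    then smoothed again, and ``u`` is the arc-length projection of (x, y)
    onto the turn-specific figure-8 loop.
    """
    geometry = geometry or TMazeGeometry()
    t = position["t_s"].to_numpy()
    bin_s = float(edges[1] - edges[0])
    step = max(1, int(round(bin_s / POSITION_DT)))

    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.searchsorted(t, edges[:-1], side="left")
    valid = idx < len(t)
    if not np.all(valid):
        warnings.warn("bins beyond tracking range dropped", stacklevel=2)
    idx = idx[valid]
    centers = centers[valid]
    del step  # sampling is by bin edge lookup; equivalent to every-20th at 512 ms

    x = gaussian_filter1d(position["x_cm"].to_numpy()[idx], smooth_sigma_bins, mode="reflect")
    y = gaussian_filter1d(position["y_cm"].to_numpy()[idx], smooth_sigma_bins, mode="reflect")
    disp = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2)
    speed = np.concatenate([[0.0], disp / bin_s])
    speed = gaussian_filter1d(speed, smooth_sigma_bins, mode="reflect")
    hd = (
        position["hd_rad"].to_numpy()[idx]
        if "hd_rad" in position.columns
        else np.full(len(idx), np.nan)
    )

    turn = np.full(len(centers), "", dtype=object)
    trial_idx = np.full(len(centers), -1)
    in_box = np.zeros(len(centers), dtype=bool)
    u = np.full(len(centers), np.nan)
    if task == "tmaze" and trials is not None and len(trials):
        tr = trials.sort_values("idx").reset_index(drop=True)
        bounds = tr["box_t0"].to_numpy()
        k = np.clip(np.searchsorted(bounds, centers, side="right") - 1, 0, len(tr) - 1)
        trial_idx = tr["idx"].to_numpy()[k]
        turn = tr["turn"].to_numpy()[k].astype(object)
        in_box = (centers >= tr["box_t0"].to_numpy()[k]) & (centers < tr["box_t1"].to_numpy()[k])
        for direction in ("L", "R"):
            m = turn == direction
            if np.any(m):
                u[m], _ = geometry.linearize(x[m], y[m], direction)
    in_reward = (u >= REWARD_U[0]) & (u < REWARD_U[1])
    in_box_u = (u >= BOX_U[0]) & (u < BOX_U[1])
    frame = pd.DataFrame(
        {
            "t_s": centers, "x_cm": x, "y_cm": y, "speed_cms": speed, "u": u,
            "turn": turn, "hd_rad": hd, "trial": trial_idx,
            "in_box": in_box | in_box_u, "in_reward": in_reward,
        }
    )
    return BehaviorSeries(frame=frame)


def equalize_head_direction(
    hd: np.ndarray,
    choice: np.ndarray,
    rng: np.random.Generator,
    hd_bin_deg: float = 20.0,
) -> np.ndarray:
    """Subsample start-box bins so L/R head-direction histograms match.

    Within each head-direction bin, the choice with the larger count has
    bins removed at random until counts are equal.  Returns a boolean mask
    over the input bins.
    """
    hd = np.asarray(hd, dtype=float)
    choice = np.asarray(choice)
    labels = np.unique(choice)
    if len(labels) != 2:
        raise ValueError("need exactly two choice labels")
    width = np.deg2rad(hd_bin_deg)
    hd_bin = np.floor(((hd + np.pi) % (2 * np.pi)) / width).astype(int)
    keep = np.ones(len(hd), dtype=bool)
    for b in np.unique(hd_bin):
        sel = hd_bin == b
        n0 = int(np.sum(sel & (choice == labels[0])))
        n1 = int(np.sum(sel & (choice == labels[1])))
        if n0 == n1:
            continue
        excess_label = labels[0] if n0 > n1 else labels[1]
        excess_idx = np.flatnonzero(sel & (choice == excess_label))
        drop = rng.choice(excess_idx, size=abs(n0 - n1), replace=False)
        keep[drop] = False
    return keep


def smoothed(activity: BinnedActivity, sigma_bins: float) -> BinnedActivity:
    """Return a copy with additional Gaussian smoothing along time."""
    rates = gaussian_filter1d(activity.rates, sigma_bins, axis=0, mode="reflect")
    total = activity.ledger.smooth_sigma_bins + sigma_bins
    return BinnedActivity(
        edges=activity.edges.copy(), rates=rates, unit_ids=activity.unit_ids.copy(),
        ledger=replace(activity.ledger, smooth_sigma_bins=total),
    )
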