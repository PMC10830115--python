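"""Synthetic behavior, tuned spiking populations and sleep LFP.

The generator emulates the study conditions that every downstream stage is
validated against: T-maze alternation with ~8-s start-box holds in a
118 cm x 118 cm arena (or open-field foraging in the same arena), CA1-like
sparse place-cell populations (~1.43 Hz mean rate, 1-2 narrow fields per
turn direction, weak conjunctive modulation) versus SUB-like high-rate
mixed-selective populations (~5.80 Hz mean, 3-6 broad left/right-congruent
fields plus axis, reward, choice and speed gains), inhomogeneous-Poisson
spiking at the 25.6-ms tracking resolution, and post-task sleep LFP with
injected 140-230 Hz ripple bursts carrying either awake-pattern
reactivation (CA1-like) or reward-biased reconfiguration (SUB-like).

Every public function takes an integer seed and is bit-reproducible from
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .maze import ARENA_CM, BOX_HOLD_U, BOX_HOLD_XY, REWARD_U, TMazeGeometry
from .session import POSITION_DT, Session, SpikeTable

CA1_MEAN_RATE_HZ = 1.43
SUB_MEAN_RATE_HZ = 5.80
RUN_SPEED_REF = 30.0  # cm/s; speed at which the speed factor is 1


# ---------------------------------------------------------------------------
# containers


@dataclass
class BehaviorSim:
    """Simulated trajectory with per-frame latent variables."""

    task: str
    position: pd.DataFrame  # t_s, x_cm, y_cm, hd_rad at 39.0625 Hz
    latents: pd.DataFrame   # u, turn, speed_cms, in_box, trial per frame
    trials: pd.DataFrame | None
    arena_cm: float = ARENA_CM

    @property
    def duration(self) -> float:
        return float(len(self.position) * POSITION_DT)


@dataclass
class TuningModel:
    """Per-unit tuning: place fields plus conjunctive gain terms."""

    profile: str               # CA1like | SUBlike
    region: str                # CA1 | SUB
    n_units: int
    baseline: np.ndarray       # Hz
    track_fields: list         # per unit: dict(center, width, gain, turn)
    of_fields: list            # per unit: dict(center (m,2), width, gain)
    turn_gain: np.ndarray      # (n, 2) multiplicative L/R gain on shared fields
    axis_pref: np.ndarray
    axis_mod: np.ndarray
    reward_gain: np.ndarray
    choice_gain: np.ndarray    # signed; active only during the box hold
    speed_mod: np.ndarray
    coact_load: np.ndarray     # (n, 2) loadings on the choice-coupled shared
                               # gain fluctuation during the box hold (L, R)
    mean_rate_hz: np.ndarray   # calibrated per-unit mean awake rate
    seed: int = 0

    def scale_units(self, factors: np.ndarray) -> None:
        self.baseline = self.baseline * factors
        self.reward_gain = self.reward_gain * factors
        for i, f in enumerate(factors):
            self.track_fields[i]["gain"] = self.track_fields[i]["gain"] * f
            self.of_fields[i]["gain"] = self.of_fields[i]["gain"] * f


@dataclass
class GroundTruth:
    """Generator-side truth for downstream recovery tests."""

    seed: int
    params: dict
    latents: pd.DataFrame | None = None
    ripple_peaks_s: np.ndarray | None = None
    ripple_content: pd.DataFrame | None = None


@dataclass
class SleepSim:
    lfp: np.ndarray
    fs: float
    spikes: SpikeTable
    truth: GroundTruth


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    task: str,
    seed: int,
    duration_s: float = 1200.0,
    run_speed_mean: float = 22.0,
    run_speed_sd: float = 8.0,
    box_hold_mean_s: float = 8.0,
    box_hold_sd_s: float = 2.0,
    error_prob: float = 0.05,
    geometry: TMazeGeometry | None = None,
) -> BehaviorSim:
    """Simulate a trajectory at the 25.6-ms tracking resolution."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if task == "tmaze":
        return _simulate_tmaze(
            seed, duration_s, run_speed_mean, run_speed_sd,
            box_hold_mean_s, box_hold_sd_s, error_prob, geometry or TMazeGeometry(),
        )
    if task == "openfield":
        return _simulate_openfield(seed, duration_s)
    raise ValueError(f"unknown task {task!r}")


def _simulate_tmaze(seed, duration_s, v_mean, v_sd, hold_mean, hold_sd, p_err, geom):
    rng = np.random.default_rng(seed)
    dt = POSITION_DT
    n_frames = int(round(duration_s / dt))
    total_len = geom.total_length("R")

    rows_xy, rows_hd = [], []
    rows_u, rows_turn, rows_speed, rows_box, rows_trial = [], [], [], [], []
    trials = []

    frame = 0
    trial = 0
    prev_turn = "R" if rng.random() < 0.5 else "L"
    jitter = np.zeros(2)
    while frame < n_frames:
        # upcoming choice: alternate, except on injected error trials
        alternate = rng.random() >= p_err
        turn = ({"L": "R", "R": "L"}[prev_turn]) if alternate else prev_turn
        correct = turn != prev_turn if trial > 0 else True

        n_hold = max(int(round(rng.normal(hold_mean, hold_sd) / dt)), int(2.0 / dt))
        box_t0 = frame * dt
        cx = BOX_HOLD_XY[0] if turn != "?" else BOX_HOLD_XY[0]
        hd_bias = 0.25 if turn == "L" else -0.25
        for _ in range(n_hold):
            if frame >= n_frames:
                break
            jitter = jitter + (-0.5 * jitter * dt + 0.8 * np.sqrt(dt) * rng.standard_normal(2))
            rows_xy.append((cx + jitter[0], BOX_HOLD_XY[1] + jitter[1]))
            rows_hd.append(np.pi / 2 + hd_bias + rng.normal(0, 0.35))
            rows_u.append(BOX_HOLD_U)
            rows_turn.append(turn)
            rows_speed.append(0.0)
            rows_box.append(True)
            rows_trial.append(trial)
            frame += 1
        box_t1 = frame * dt
        trials.append((trial, turn, bool(correct), box_t0, box_t1))

        # run the loop: box -> stem -> junction -> arm -> reward -> return
        s = 10.0  # arc length of the hold point along the loop (box rear + 10 cm)
        v = max(rng.normal(v_mean, v_sd), 10.0)
        lat = np.zeros(2)
        drank = False
        while s < total_len - 1.0 and frame < n_frames:
            u_now = float(geom.u_at_arclength(s, turn)[0])
            if not drank and u_now >= 0.88:
                # pause at the water port to drink
                drank = True
                n_pause = int(max(rng.normal(1.8, 0.8), 0.3) / dt)
                xy0, tangent = geom.point_at_arclength(s, turn)
                hd0 = float(np.arctan2(tangent[0, 1], tangent[0, 0]))
                for _ in range(n_pause):
                    if frame >= n_frames:
                        break
                    rows_xy.append(tuple(xy0[0] + rng.normal(0, 0.5, 2)))
                    rows_hd.append(hd0 + rng.normal(0, 0.2))
                    rows_u.append(u_now)
                    rows_turn.append(turn)
                    rows_speed.append(0.0)
                    rows_box.append(False)
                    rows_trial.append(trial)
                    frame += 1
                continue
            if rng.random() < 0.25 * dt:
                # brief hesitation (sniffing, checking) somewhere on the loop
                xy0, tangent = geom.point_at_arclength(s, turn)
                hd0 = float(np.arctan2(tangent[0, 1], tangent[0, 0]))
                for _ in range(int(max(rng.normal(1.0, 0.5), 0.2) / dt)):
                    if frame >= n_frames:
                        break
                    rows_xy.append(tuple(xy0[0] + rng.normal(0, 0.5, 2)))
                    rows_hd.append(hd0 + rng.normal(0, 0.25))
                    rows_u.append(u_now)
                    rows_turn.append(turn)
                    rows_speed.append(0.0)
                    rows_box.append(False)
                    rows_trial.append(trial)
                    frame += 1
                continue
            if s > total_len - 12.0 and rng.random() < 0.6 * dt:
                # linger near the box entrance before re-entering
                xy0, tangent = geom.point_at_arclength(s, turn)
                hd0 = float(np.arctan2(tangent[0, 1], tangent[0, 0]))
                for _ in range(int(max(rng.normal(2.0, 1.5), 0.2) / dt)):
                    if frame >= n_frames:
                        break
                    rows_xy.append(tuple(xy0[0] + rng.normal(0, 0.5, 2)))
                    rows_hd.append(hd0 + rng.normal(0, 0.3))
                    rows_u.append(u_now)
                    rows_turn.append(turn)
                    rows_speed.append(0.0)
                    rows_box.append(False)
                    rows_trial.append(trial)
                    frame += 1
                s += 1.0
                continue
            v += 1.0 * (v_mean - v) * dt + v_sd * np.sqrt(dt) * rng.standard_normal()
            v = float(np.clip(v, 8.0, 80.0))
            s += v * dt
            xy, tangent = geom.point_at_arclength(min(s, total_len - 1e-6), turn)
            lat = lat + (-1.5 * lat * dt + 1.0 * np.sqrt(dt) * rng.standard_normal(2))
            rows_xy.append(tuple(xy[0] + lat))
            rows_hd.append(float(np.arctan2(tangent[0, 1], tangent[0, 0]) + rng.normal(0, 0.12)))
            rows_u.append(float(geom.u_at_arclength(s, turn)[0]))
            rows_turn.append(turn)
            rows_speed.append(v)
            rows_box.append(False)
            rows_trial.append(trial)
            frame += 1
        prev_turn = turn
        trial += 1

    t = np.arange(n_frames) * dt
    xy = np.array(rows_xy[:n_frames])
    position = pd.DataFrame(
        {"t_s": t, "x_cm": xy[:, 0], "y_cm": xy[:, 1], "hd_rad": rows_hd[:n_frames]}
    )
    latents = pd.DataFrame(
        {
            "u": rows_u[:n_frames], "turn": rows_turn[:n_frames],
            "speed_cms": rows_speed[:n_frames], "in_box": rows_box[:n_frames],
            "trial": rows_trial[:n_frames],
        }
    )
    trials_df = pd.DataFrame(trials, columns=["idx", "turn", "correct", "box_t0", "box_t1"])
    # drop a trailing trial whose box hold was cut off by the session end
    trials_df = trials_df[trials_df["box_t1"] <= duration_s + 1e-9].reset_index(drop=True)
    return BehaviorSim(task="tmaze", position=position, latents=latents, trials=trials_df)


def _simulate_openfield(seed, duration_s, margin: float = 4.0, sigma_v: float = 18.0):
    rng = np.random.default_rng(seed)
    dt = POSITION_DT
    n = int(round(duration_s / dt))
    xy = np.empty((n, 2))
    v = np.zeros(2)
    pos = np.array([ARENA_CM / 2, ARENA_CM / 2])
    lo, hi = margin, ARENA_CM - margin
    for i in range(n):
        v += -0.5 * v * dt + sigma_v * np.sqrt(dt) * rng.standard_normal(2)
        pos = pos + v * dt
        for k in range(2):  # reflective walls
            if pos[k] < lo:
                pos[k] = 2 * lo - pos[k]
                v[k] = -v[k]
            elif pos[k] > hi:
                pos[k] = 2 * hi - pos[k]
                v[k] = -v[k]
        xy[i] = pos
    speed = np.linalg.norm(v := np.gradient(xy, dt, axis=0), axis=1)
    hd = np.arctan2(v[:, 1], v[:, 0]) + rng.normal(0, 0.12, n)
    t = np.arange(n) * dt
    position = pd.DataFrame({"t_s": t, "x_cm": xy[:, 0], "y_cm": xy[:, 1], "hd_rad": hd})
    latents = pd.DataFrame(
        {"u": np.nan, "turn": "", "speed_cms": speed, "in_box": False, "trial": 0}, index=range(n)
    )
    return BehaviorSim(task="openfield", position=position, latents=latents, trials=None)


# ---------------------------------------------------------------------------
# tuning models


def build_population(
    profile: str,
    n_units: int,
    seed: int,
    task: str = "tmaze",
    calibrate: bool = True,
) -> TuningModel:
    """Draw a tuned population and calibrate its mean rate to the regional target.

    CA1-like units carry 1-2 narrow place fields per turn direction drawn
    independently for left and right loops; SUB-like units carry 3-6 broad
    fields shared between the loops (left/right congruent) plus axis,
    reward, choice and speed gains, which drives the bent-figure-8 manifold
    geometry downstream.  Per-unit mean rates are log-normally dispersed
    around 1.43 Hz (CA1-like) or 5.80 Hz (SUB-like) and calibrated against
    a reference behavior simulated internally.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if profile not in ("CA1like", "SUBlike"):
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    ca1 = profile == "CA1like"
    geom = TMazeGeometry()
    total_len = geom.total_length("R")

    def _draw_centers(m):
        # field centers uniform over the physical ground (arc length), then
        # expressed on the linearized coordinate
        s = rng.uniform(0.02, 0.98, m) * total_len
        return np.asarray(geom.u_at_arclength(s, "R"))

    track_fields, of_fields = [], []
    for _ in range(n_units):
        if ca1:
            # spatial fields: box/stem ground is shared by both loops, so
            # fields with centers before the junction fire on either turn;
            # arm/return fields are inherently turn-specific
            m = int(rng.integers(1, 4))
            c = _draw_centers(m)
            tn = np.where(
                c < 0.55, "B", rng.choice(["L", "R"], m)
            ).astype(object)
            track_fields.append(
                {"center": c, "width": rng.uniform(0.025, 0.06, m),
                 "gain": rng.lognormal(np.log(14.0), 0.4, m), "turn": tn}
            )
            m = rng.integers(1, 3)
            of_fields.append(
                {"center": rng.uniform(8, ARENA_CM - 8, (m, 2)),
                 "width": rng.uniform(6, 11, m),
                 "gain": rng.lognormal(np.log(8.0), 0.4, m)}
            )
        else:
            # conjunctive mixed selectivity: every unit blends congruent
            # (axis/reward-like, fires on both loops) and turn-specific
            # (place-like) components; fields on the shared box/stem ground
            # are congruent by construction
            m = int(rng.integers(3, 7))
            c = _draw_centers(m)
            w = rng.uniform(0.08, 0.2, m)
            g = rng.lognormal(np.log(6.0), 0.4, m)
            congruence = rng.uniform(0.15, 0.85)  # per-unit propensity
            # axis/reward-driven congruence holds on stem, arms and reward,
            # but the return legs (opposite walls, mirrored headings) are
            # inherently turn-specific
            shared = (c < 0.90) & ((c < 0.55) | (rng.random(m) < congruence))
            tn = np.where(shared, "B", rng.choice(["L", "R"], m)).astype(object)
            track_fields.append({"center": c, "width": w, "gain": g, "turn": tn})
            m2 = rng.integers(3, 7)
            of_fields.append(
                {"center": rng.uniform(8, ARENA_CM - 8, (m2, 2)),
                 "width": rng.uniform(14, 30, m2),
                 "gain": rng.lognormal(np.log(6.0), 0.4, m2)}
            )

    model = TuningModel(
        profile=profile,
        region="CA1" if ca1 else "SUB",
        n_units=n_units,
        baseline=np.full(n_units, 0.1 if ca1 else 1.2),
        track_fields=track_fields,
        of_fields=of_fields,
        turn_gain=(
            np.ones((n_units, 2))
            if ca1 else np.exp(rng.normal(0.0, 0.15, (n_units, 2)))
        ),
        axis_pref=rng.uniform(0, np.pi, n_units),
        axis_mod=rng.uniform(0.0, 0.1, n_units) if ca1 else rng.uniform(0.25, 0.6, n_units),
        reward_gain=(
            np.where(rng.random(n_units) < 0.1, rng.uniform(0.5, 2.0, n_units), 0.0)
            if ca1 else
            np.where(rng.random(n_units) < 0.45, rng.uniform(6.0, 14.0, n_units), 0.0)
        ),
        choice_gain=(
            rng.uniform(-0.1, 0.1, n_units) if ca1
            else rng.uniform(0.15, 0.4, n_units) * rng.choice([-1.0, 1.0], n_units)
        ),
        speed_mod=rng.uniform(0.0, 0.15, n_units) if ca1 else rng.uniform(0.1, 0.4, n_units),
        coact_load=rng.normal(0.0, 0.15 if ca1 else 0.35, (n_units, 2)),
        mean_rate_hz=np.zeros(n_units),
        seed=seed,
    )

    target_mean = CA1_MEAN_RATE_HZ if ca1 else SUB_MEAN_RATE_HZ
    targets = target_mean * np.exp(rng.normal(0, 0.4, n_units) - 0.08)
    if calibrate:
        ref = simulate_behavior(task, seed=int((seed * 7919 + 13) % 2**31), duration_s=240.0)
        lam = tuning_rates(model, ref)
        measured = lam.mean(axis=0)
        measured[measured <= 0] = 1e-6
        model.scale_units(targets / measured)
    model.mean_rate_hz = targets
    return model


def _track_rate(model: TuningModel, i: int, u: np.ndarray, turn: np.ndarray) -> np.ndarray:
    f = model.track_fields[i]
    lam = np.zeros(len(u))
    tg = np.where(turn == "L", model.turn_gain[i, 0], model.turn_gain[i, 1])
    for c, w, g, tn in zip(f["center"], f["width"], f["gain"], f["turn"]):
        bump = g * np.exp(-0.5 * ((u - c) / w) ** 2)
        if tn == "B":
            lam += tg * bump  # shared field, slightly turn-modulated
        else:
            lam += np.where(turn == tn, bump, 0.0)
    return lam


def tuning_rates(model: TuningModel, behavior: BehaviorSim) -> np.ndarray:
    """Instantaneous rate (Hz) of every unit at every tracking frame."""
    lat = behavior.latents
    n_frames = len(lat)
    hd = behavior.position["hd_rad"].to_numpy()
    speed = lat["speed_cms"].to_numpy()
    in_box = lat["in_box"].to_numpy()
    turn = lat["turn"].to_numpy()
    u = lat["u"].to_numpy()
    choice_sign = np.where(turn == "L", 1.0, -1.0)

    lam = np.empty((n_frames, model.n_units))
    for i in range(model.n_units):
        if behavior.task == "tmaze":
            base = model.baseline[i] + _track_rate(model, i, u, turn)
            base = base + model.reward_gain[i] * ((u >= REWARD_U[0]) & (u < REWARD_U[1]))
        else:
            f = model.of_fields[i]
            xy = behavior.position[["x_cm", "y_cm"]].to_numpy()
            base = np.full(n_frames, model.baseline[i])
            for c, w, g in zip(f["center"], f["width"], f["gain"]):
                d2 = ((xy - c) ** 2).sum(axis=1)
                base = base + g * np.exp(-0.5 * d2 / w**2)
        f_axis = (1 - model.axis_mod[i]) + 2 * model.axis_mod[i] * np.cos(hd - model.axis_pref[i]) ** 2
        f_speed = np.clip(1 + model.speed_mod[i] * (speed / RUN_SPEED_REF - 1), 0.3, None)
        f_choice = np.where(in_box, 1 + model.choice_gain[i] * choice_sign, 1.0)
        lam[:, i] = np.clip(base * f_axis * f_speed * f_choice, 0.0, None)
    return lam


def rate_at(model: TuningModel, u: float, turn: str, speed: float = RUN_SPEED_REF,
            geometry: TMazeGeometry | None = None) -> np.ndarray:
    """Population rate vector at one point of the T-maze loop (running)."""
    geometry = geometry or TMazeGeometry()
    s = np.interp(u, geometry.waypoint_u, geometry._segments(turn)[3])
    _, tangent = geometry.point_at_arclength(s, turn)
    hd = float(np.arctan2(tangent[0, 1], tangent[0, 0]))
    uu = np.array([u])
    tt = np.array([turn], dtype=object)
    lam = np.empty(model.n_units)
    for i in range(model.n_units):
        base = model.baseline[i] + _track_rate(model, i, uu, tt)[0]
        base += model.reward_gain[i] * (REWARD_U[0] <= u < REWARD_U[1])
        f_axis = (1 - model.axis_mod[i]) + 2 * model.axis_mod[i] * np.cos(hd - model.axis_pref[i]) ** 2
        f_speed = np.clip(1 + model.speed_mod[i] * (speed / RUN_SPEED_REF - 1), 0.3, None)
        lam[i] = max(base * f_axis * f_speed, 0.0)
    return lam


def rate_maps(model: TuningModel, n_u: int = 50) -> dict:
    """Turn-conditioned rate maps on a linearized-position grid (units x bins)."""
    grid = (np.arange(n_u) + 0.5) / n_u
    out = {}
    for turn in ("L", "R"):
        out[turn] = np.stack([rate_at(model, float(u), turn) for u in grid], axis=1)
    return out


# ---------------------------------------------------------------------------
# spiking


def generate_spikes(model: TuningModel, behavior: BehaviorSim, seed: int):
    """Inhomogeneous-Poisson spikes per 25.6-ms frame; returns (SpikeTable, GroundTruth)."""
    rng = np.random.default_rng(seed)
    lam = tuning_rates(model, behavior)
    if np.any(lam < 0):
        raise ValueError("negative rates in tuning model")
    dt = POSITION_DT

    # choice-coupled ensemble co-fluctuation during the box hold: a shared
    # slow gain z(t) loads onto units with choice-dependent weights, so the
    # upcoming turn is also carried by pairwise coactivity, not only by
    # mean rates
    lat = behavior.latents
    in_box = lat["in_box"].to_numpy()
    if np.any(in_box):
        n_frames = len(lat)
        z = np.empty(n_frames)
        z[0] = rng.standard_normal()
        tau = 1.0
        a = np.exp(-dt / tau)
        z[1:] = rng.standard_normal(n_frames - 1)
        for k in range(1, n_frames):
            z[k] = a * z[k - 1] + np.sqrt(1 - a * a) * z[k]
        side = (lat["turn"].to_numpy() == "R").astype(int)
        load = model.coact_load[:, side].T  # frames x units
        gain = np.exp(load * z[:, None] - 0.5 * load**2)
        lam = np.where(in_box[:, None], lam * gain, lam)
    t0 = behavior.position["t_s"].to_numpy()
    counts = rng.poisson(lam * dt)
    frames, units = np.nonzero(counts)
    reps = counts[frames, units]
    unit_col = np.repeat(units, reps)
    t_col = np.repeat(t0[frames], reps) + rng.uniform(0, dt, reps.sum())
    order = np.lexsort((t_col, unit_col))
    spikes = pd.DataFrame({"unit_id": unit_col[order], "t_s": t_col[order]})

    duration = behavior.duration
    widths = 0.55 + np.clip(np.random.default_rng(model.seed + 1).normal(0, 0.04, model.n_units), -0.08, 0.3)
    measured = np.array([(spikes["unit_id"] == i).sum() / duration for i in range(model.n_units)])
    units_df = pd.DataFrame(
        {
            "unit_id": np.arange(model.n_units),
            "region": model.region,
            "width_ms": widths,
            "rate_hz": measured,
            "iso_dist": 35.0,
            "isi_idx": 0.05,
            "amp_uv": 120.0,
        }
    )
    truth = GroundTruth(
        seed=seed,
        params={"profile": model.profile, "n_units": model.n_units},
        latents=behavior.latents.copy(),
    )
    return SpikeTable(spikes=spikes, units=units_df), truth


# ---------------------------------------------------------------------------
# sleep


def simulate_sleep(
    model: TuningModel,
    seed: int,
    duration_s: float = 600.0,
    fs: float = 1250.0,
    ripple_rate_hz: float = 0.3,
    burst_sigma_s: float = 0.025,
    osc_freq_hz: float = 170.0,
    snr: float = 8.0,
    background_rate_frac: float = 0.2,
    reactivation_gain: float | None = None,
) -> SleepSim:
    """Post-task sleep: 1/f LFP with injected ripple bursts and event spiking.

    During each burst the population either reactivates an awake pattern at
    a random track location (CA1-like) or re-expresses a reward-anchored
    pattern passed through a fixed multiplicative distortion (SUB-like),
    which moves the event vectors off the awake manifold while keeping them
    tightly clustered and reward-associated.
    """
    if fs < 2 * 230.0:
        raise ValueError("sampling rate below Nyquist for the 140-230 Hz ripple band")
    rng = np.random.default_rng(seed)
    if reactivation_gain is None:
        # ripple gain is strong in CA1 pyramidal cells and more modest in
        # the already high-rate subicular population
        reactivation_gain = 6.0 if model.profile == "CA1like" else 2.5
    n = int(round(duration_s * fs))

    # 1/f background, unit variance
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec /= np.sqrt(np.maximum(freqs, 1.0))
    lfp = np.fft.irfft(spec, n)
    lfp /= lfp.std()

    b, a = butter(3, [140.0 / (fs / 2), 230.0 / (fs / 2)], btype="bandpass")
    sigma_band = float(np.std(filtfilt(b, a, lfp)))
    amp = snr * sigma_band

    # ripple times: Poisson with a 350-ms refractory gap
    peaks = []
    t = 5.0
    while True:
        t += max(rng.exponential(1.0 / ripple_rate_hz), 0.35)
        if t >= duration_s - 5.0:
            break
        peaks.append(t)
    peaks = np.array(peaks)

    tvec = np.arange(n) / fs
    for t0 in peaks:
        i0, i1 = int((t0 - 4 * burst_sigma_s) * fs), int((t0 + 4 * burst_sigma_s) * fs)
        tt = tvec[i0:i1]
        lfp[i0:i1] += amp * np.exp(-0.5 * ((tt - t0) / burst_sigma_s) ** 2) * np.sin(
            2 * np.pi * osc_freq_hz * (tt - t0)
        )

    # spiking: low-rate background plus event bursts
    bg_rates = background_rate_frac * model.mean_rate_hz
    unit_col, t_col = [], []
    for i in range(model.n_units):
        k = rng.poisson(bg_rates[i] * duration_s)
        t_col.append(rng.uniform(0, duration_s, k))
        unit_col.append(np.full(k, i))

    half = 0.0384  # half of the 76.8-ms ripple analysis bin
    ca1 = model.profile == "CA1like"
    # reconfiguration (SUB-like): a fixed multiplicative distortion that
    # up-weights reward-gain units and perturbs the rest, applied to the
    # reward-zone pattern on every event
    distort = np.exp(rng.normal(0.0, 0.35, model.n_units)) * np.where(
        model.reward_gain > 0, 1.4, 0.85
    )
    content = []
    for t0 in peaks:
        turn = "L" if rng.random() < 0.5 else "R"
        if ca1:
            u_evt = float(rng.uniform(0.08, 0.97))
            lam_evt = reactivation_gain * rate_at(model, u_evt, turn)
        else:
            # reward pattern as experienced during consumption (speed ~ 0),
            # anchored at the water port
            u_evt = float(np.clip(rng.normal(0.885, 0.005), *REWARD_U))
            jitter = np.exp(rng.normal(0.0, 0.2, model.n_units))
            lam_evt = (reactivation_gain * distort * jitter
                       * rate_at(model, u_evt, turn, speed=0.0))
        k = rng.poisson(lam_evt * 2 * half)
        for i in np.nonzero(k)[0]:
            t_col.append(t0 - half + rng.uniform(0, 2 * half, k[i]))
            unit_col.append(np.full(k[i], i))
        content.append((t0, u_evt, turn))

    unit_col = np.concatenate(unit_col) if unit_col else np.empty(0, int)
    t_col = np.concatenate(t_col) if t_col else np.empty(0)
    order = np.lexsort((t_col, unit_col))
    spikes = pd.DataFrame({"unit_id": unit_col[order].astype(int), "t_s": t_col[order]})
    units_df = pd.DataFrame(
        {
            "unit_id": np.arange(model.n_units),
            "region": model.region,
            "width_ms": 0.55,
            "rate_hz": np.array([(spikes["unit_id"] == i).sum() / duration_s
                                 for i in range(model.n_units)]),
        }
    )
    truth = GroundTruth(
        seed=seed,
        params={"duration_s": duration_s, "fs": fs, "ripple_rate_hz": ripple_rate_hz,
                "osc_freq_hz": osc_freq_hz, "snr": snr},
        ripple_peaks_s=peaks,
        ripple_content=pd.DataFrame(content, columns=["peak_s", "u", "turn"]),
    )
    return SleepSim(lfp=lfp, fs=fs, spikes=SpikeTable(spikes=spikes, units=units_df), truth=truth)


# ---------------------------------------------------------------------------
# convenience: one call -> full session


def make_session(
    profile: str,
    task: str = "tmaze",
    n_units: int = 30,
    seed: int = 0,
    duration_s: float = 1200.0,
    with_sleep: bool = False,
    sleep_duration_s: float = 600.0,
    **behavior_kwargs,
):
    """Simulate behavior + population + spikes (+ optional sleep) as a Session."""
    behavior = simulate_behavior(task, seed=seed, duration_s=duration_s, **behavior_kwargs)
    model = build_population(profile, n_units, seed=seed + 1, task=task)
    spike_table, truth = generate_spikes(model, behavior, seed=seed + 2)
    session = Session(
        spikes=spike_table, position=behavior.position, trials=behavior.trials, task=task
    )
    sleep = None
    if with_sleep:
        sleep = simulate_sleep(model, seed=seed + 3, duration_s=sleep_duration_s)
        session.lfp = sleep.lfp
        session.lfp_fs = sleep.fs
    return session, model, truth, sleep
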