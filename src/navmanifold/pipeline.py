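"""Config-driven orchestration of the full analysis with machine-readable reports.

A run is described by a ``RunConfig`` (loadable from YAML): where the
session comes from (a directory on disk or the synthetic generator), which
stages to execute, per-stage seeds and the handful of analysis parameters
that matter.  ``run_pipeline`` executes the requested stages in dependency
order and writes a JSON summary plus TSV tables; identical configs produce
byte-identical summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decode as dec
from . import ripple as rip
from . import shape as shp
from .dimension import estimate_dimension
from .embed import embed, joint_embed
from .session import (
    Session,
    bin_activity,
    classify_units,
    derive_behavior,
    read_session,
    select_session,
)
from .synth import make_session
from .topology import TopologyParams, density_filter, robust_holes

KNOWN_STAGES = ("dimension", "topology", "shape", "decode", "ripple")


@dataclass
class RunConfig:
    session_dir: str | None = None
    synth: dict | None = None          # kwargs for synth.make_session
    task: str = "tmaze"
    region: str | None = None
    stages: tuple = KNOWN_STAGES
    bin_s: float = 0.512
    embed_method: str = "isomap"
    embed_d: int = 3
    n_neighbors: int = 20
    zscore: bool = False
    topology_shuffles: int = 50
    topology_landmarks: int = 64
    topology_maxdim: int = 2
    decode_shuffles: int = 0
    ripple_n_events: int = 100
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        bad = set(cfg.stages) - set(KNOWN_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunReport:
    config: RunConfig
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.summary, sort_keys=True, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _load(cfg: RunConfig):
    if cfg.session_dir is not None:
        session = read_session(cfg.session_dir, task=cfg.task)
        return session, None
    if cfg.synth is not None:
        synth_kwargs = dict(cfg.synth)
        synth_kwargs.setdefault("seed", cfg.seed)
        synth_kwargs.setdefault("task", cfg.task)
        session, _model, _truth, sleep = make_session(**synth_kwargs)
        return session, sleep
    raise ValueError("config needs session_dir or synth")


def run_pipeline(cfg: RunConfig) -> RunReport:
    session, sleep = _load(cfg)
    report = RunReport(config=cfg)
    s = report.summary
    s["parameters"] = {k: v for k, v in asdict(cfg).items() if k != "out_dir"}

    labels = classify_units(session.spikes.units)
    principal = session.spikes.units.loc[
        labels.str.endswith("principal"), "unit_id"
    ].tolist()
    region = cfg.region or session.spikes.units["region"].iloc[0]
    s["n_principal_units"] = len(principal)
    s["session_selected"] = bool(select_session(session.spikes.units, region))
    spikes = session.spikes.subset(principal)

    interval = (0.0, session.t_end)
    binned = bin_activity(spikes, interval, bin_s=cfg.bin_s, sqrt=True, zscore=cfg.zscore)
    smoothed = bin_activity(
        spikes, interval, bin_s=cfg.bin_s, sqrt=True, smooth_sigma_bins=2.0, zscore=cfg.zscore
    )
    behavior = derive_behavior(session.position, session.trials, binned.edges, task=session.task)

    if "dimension" in cfg.stages:
        ci = estimate_dimension(binned.rates)
        s["dimension"] = {"alpha": ci.alpha, "fit_r2": ci.fit_r2,
                          "n_bins": binned.n_bins, "n_units": binned.n_units}

    emb_geo = None
    if {"topology", "shape"} & set(cfg.stages):
        emb_geo = embed(smoothed, method=cfg.embed_method, d=cfg.embed_d,
                        n_neighbors=cfg.n_neighbors)

    if "topology" in cfg.stages:
        params = TopologyParams(
            bin_s=cfg.bin_s, d=cfg.embed_d, n_neighbors=cfg.n_neighbors,
            maxdim=cfg.topology_maxdim, n_landmarks=cfg.topology_landmarks,
        )
        res = robust_holes(spikes, interval, params, n_shuffle=cfg.topology_shuffles,
                           seed=cfg.seed)
        s["topology"] = {
            "robust_counts": {f"H{q}": v for q, v in sorted(res.robust_counts.items())},
            "null_threshold": {f"H{q}": v for q, v in sorted(res.null_threshold.items())},
        }

    if "shape" in cfg.stages:
        cloud = density_filter(emb_geo.coords)
        sig = shp.d2_distribution(cloud, apply_density_filter=False)
        entry = {"bimodality_b": sig.b, "dissimilarity": {}}
        for kind in ("sphere", "figure8", "bent_figure8"):
            model = shp.make_feature_model(kind, n=2000, seed=cfg.seed)
            entry["dissimilarity"][kind] = shp.dissimilarity(
                sig, shp.d2_distribution(model.points, apply_density_filter=False)
            )
        if session.task == "tmaze":
            pv = shp.pv_correlation(binned, behavior)
            arm_r = pv.attrs["arm_r"]
            entry["mean_pv_r"] = float(np.nanmean(pv["pv_r"]))
            entry["mean_arm_tuning_r"] = float(np.nanmean(arm_r))
        s["shape"] = entry

    if "decode" in cfg.stages:
        emb_dec = embed(binned, method=cfg.embed_method, d=cfg.embed_d,
                        n_neighbors=cfg.n_neighbors)
        f = behavior.frame
        xy = f[["x_cm", "y_cm"]].to_numpy()
        pos = dec.gpr_decode(emb_dec.coords, xy, seed=cfg.seed)
        speed = dec.gpr_decode(emb_dec.coords, f["speed_cms"].to_numpy(), seed=cfg.seed)
        entry = {"position_r2": pos.accuracy, "speed_r2": speed.accuracy,
                 "position_noisiness": pos.noisiness}
        if session.task == "tmaze" and session.trials is not None:
            correct = set(session.trials.loc[session.trials["correct"], "idx"])
            box = f["in_box"].to_numpy() & np.isin(f["trial"].to_numpy(), list(correct))
            turns = dict(zip(session.trials["idx"], session.trials["turn"]))
            try:
                path = dec.decode_path(emb_dec.coords[box], f["trial"].to_numpy()[box],
                                       turns, seed=cfg.seed)
                entry["path_accuracy"] = path.accuracy
                coact = dec.coactivity_decode(binned.rates[box], f["trial"].to_numpy()[box],
                                              turns, seed=cfg.seed)
                entry["coactivity_accuracy"] = coact.accuracy
            except ValueError as err:
                warnings.warn(f"path decoding skipped: {err}", stacklevel=2)
        if cfg.decode_shuffles:
            def _decoder(tbl):
                b2 = bin_activity(tbl, interval, bin_s=cfg.bin_s, sqrt=True, zscore=cfg.zscore)
                e2 = embed(b2, method=cfg.embed_method, d=cfg.embed_d,
                           n_neighbors=cfg.n_neighbors)
                return dec.gpr_decode(e2.coords, xy, seed=cfg.seed).accuracy

            chance = dec.shuffle_chance(spikes, interval, _decoder,
                                        n_shuffle=cfg.decode_shuffles, seed=cfg.seed)
            entry["position_chance_max"] = float(chance.max())
        s["decode"] = entry

    if "ripple" in cfg.stages and session.lfp is not None:
        events = rip.detect_ripples(session.lfp, session.lfp_fs)
        entry = {"n_events": len(events), "usable": events.usable}
        sleep_spikes = sleep.spikes if sleep is not None else spikes
        if len(events) >= cfg.ripple_n_events:
            evt_bins, _ = rip.ripple_bins(sleep_spikes, events,
                                          n_events=cfg.ripple_n_events, seed=cfg.seed)
            awake_for_joint = bin_activity(spikes, interval, bin_s=cfg.bin_s, sqrt=True)
            joint = joint_embed(awake_for_joint, evt_bins, n_neighbors=cfg.n_neighbors)
            geo = rip.ripple_geometry(joint)
            entry["first3nn"] = geo.first3nn
            entry["dispersion"] = geo.dispersion
            entry["concentration_k"] = geo.k
            _, mean_shift = rip.correlation_shift(awake_for_joint, evt_bins)
            entry["mean_abs_corr_shift"] = mean_shift
            if session.task == "tmaze":
                segments = rip.build_segments(joint.awake_coords, behavior)
                obs, null = rip.segment_association(segments, joint.event_coords,
                                                    n_null=200, seed=cfg.seed,
                                                    awake_coords=joint.awake_coords)
                entry["landmark_fractions"] = obs
                entry["reward_null_p975"] = float(np.percentile(null["reward"], 97.5))
        s["ripple"] = entry

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(report.to_json())
        cfg.to_yaml(out / "config.yaml")
    return report
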