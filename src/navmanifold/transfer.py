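"""Cross-session decoding: rotation alignment and peer-neuron decoding.

A GPR position decoder trained on one session's 3-D manifold is applied to
another session (different rat, region or task) after rotating the target
manifold by the best element of SO(3).  The rotation is found on a random
half of the target bins by an Euler-angle grid search (15 degree steps)
followed by local refinement (3 degree steps); the reported accuracy is
computed on the held-out half.  Structural similarity is the ratio of
cross-decoding accuracy to the target's own twofold self-decoding
accuracy.  Peer-neuron decoding embeds N-1 units and GPR-decodes the
held-out unit's smoothed rate from the resulting manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from .decode import DecodingResult, _new_gpr, gpr_decode, r_squared
from .embed import embed
from .session import BinnedActivity

INCLUSION_MIN_ACCURACY = 0.2  # sessions must self-decode position at >= 0.2


@dataclass
class AlignmentResult:
    rotation: np.ndarray              # 3x3, det +1
    search_accuracy: float            # on the rotation-search half
    held_out_accuracy: float          # reported accuracy
    mode: str
    structural_similarity: float | None = None
    self_accuracy: float | None = None
    grid_deg: float = 15.0
    refine_deg: float = 3.0
    objective_trace: list = field(default_factory=list)  # coarse audit of the search


def _accuracy(models, coords, targets) -> float:
    r2 = [r_squared(targets[:, c], models[c].predict(coords)) for c in range(targets.shape[1])]
    return float(np.mean(r2))


def _grid(step_deg: float):
    a = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    b = np.deg2rad(np.arange(0.0, 180.0 + 1e-9, step_deg))
    return a, b


def search_rotation(
    models, coords, targets, grid_deg: float = 15.0, refine_deg: float = 3.0
):
    """Grid-then-refine search over SO(3) maximizing decoding accuracy."""
    best = (-np.inf, np.eye(3), (0.0, 0.0, 0.0))
    trace = []
    alphas, betas = _grid(grid_deg)
    for ea in alphas:
        for eb in betas:
            for eg in alphas:
                rot = Rotation.from_euler("zyz", [ea, eb, eg]).as_matrix()
                acc = _accuracy(models, coords @ rot.T, targets)
                if acc > best[0]:
                    best = (acc, rot, (ea, eb, eg))
        trace.append((np.rad2deg(ea), best[0]))
    ea0, eb0, eg0 = best[2]
    delta = np.deg2rad(np.arange(-grid_deg, grid_deg + 1e-9, refine_deg))
    for da in delta:
        for db in delta:
            for dg in delta:
                rot = Rotation.from_euler("zyz", [ea0 + da, eb0 + db, eg0 + dg]).as_matrix()
                acc = _accuracy(models, coords @ rot.T, targets)
                if acc > best[0]:
                    best = (acc, rot, (ea0 + da, eb0 + db, eg0 + dg))
    return best[0], best[1], trace


def cross_decode(
    source_coords: np.ndarray,
    source_targets: np.ndarray,
    target_coords: np.ndarray,
    target_targets: np.ndarray,
    mode: str = "across-rat",
    seed: int = 0,
    grid_deg: float = 15.0,
    refine_deg: float = 3.0,
    check_inclusion: bool = True,
    self_accuracy: float | None = None,
) -> AlignmentResult:
    """Train GPR on the source manifold, decode the target after SO(3) alignment.

    ``*_targets`` are (n, 2) X/Y positions (decoded separately, R^2
    averaged).  Both sessions must pass the >= 0.2 self-decoding inclusion
    filter (computed here when not supplied).  Half of the target bins
    (seeded split) drive the rotation search; the other half gives the
    reported accuracy.
    """
    source_coords = np.asarray(source_coords, float)
    target_coords = np.asarray(target_coords, float)
    if source_coords.shape[1] != 3 or target_coords.shape[1] != 3:
        raise ValueError("cross-session alignment requires 3-D embeddings")
    source_targets = np.atleast_2d(np.asarray(source_targets, float))
    target_targets = np.atleast_2d(np.asarray(target_targets, float))
    if source_targets.shape[0] != len(source_coords):
        source_targets = source_targets.T
    if target_targets.shape[0] != len(target_coords):
        target_targets = target_targets.T

    if self_accuracy is None:
        self_accuracy = gpr_decode(target_coords, target_targets, seed=seed).accuracy
    if check_inclusion:
        src_self = gpr_decode(source_coords, source_targets, seed=seed).accuracy
        if src_self < INCLUSION_MIN_ACCURACY or self_accuracy < INCLUSION_MIN_ACCURACY:
            raise ValueError(
                f"session below inclusion threshold ({src_self:.2f}, {self_accuracy:.2f})"
            )

    models = []
    for c in range(source_targets.shape[1]):
        gpr = _new_gpr(seed)
        gpr.fit(source_coords, source_targets[:, c])
        models.append(gpr)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(target_coords))
    half = len(perm) // 2
    search, held = perm[:half], perm[half:]

    search_acc, rot, trace = search_rotation(
        models, target_coords[search], target_targets[search], grid_deg, refine_deg
    )
    held_acc = _accuracy(models, target_coords[held] @ rot.T, target_targets[held])
    assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-6) and np.linalg.det(rot) > 0

    return AlignmentResult(
        rotation=rot, search_accuracy=search_acc, held_out_accuracy=held_acc,
        mode=mode, self_accuracy=self_accuracy,
        structural_similarity=held_acc / self_accuracy if self_accuracy else None,
        grid_deg=grid_deg, refine_deg=refine_deg, objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# peer-neuron decoding


SILENT_RATE_HZ = 0.001


def decode_peer_neuron(
    binned: BinnedActivity,
    target_unit: int,
    d: int = 3,
    n_neighbors: int = 20,
    smooth_sigma_bins: float = 1.0,
    seed: int = 0,
) -> DecodingResult:
    """Decode one unit's smoothed rate from the manifold of the remaining units.

    ``binned`` must carry unsmoothed sqrt rates.  The held-out unit's rate
    is Gaussian-smoothed (sigma = 1 bin) and decoded by twofold GPR from a
    3-D Isomap embedding of the other N-1 units.
    """
    ids = list(binned.unit_ids)
    if len(ids) < 11:
        raise ValueError("need >= 11 units")
    j = ids.index(target_unit)
    y = binned.rates[:, j]
    if (y**2).mean() < SILENT_RATE_HZ:  # y is sqrt(rate), so y^2 is the rate in Hz
        raise ValueError("target unit is silent")
    rest = np.delete(binned.rates, j, axis=1)
    emb = embed(rest, method="isomap", d=d, n_neighbors=n_neighbors)
    y_smooth = gaussian_filter1d(y, smooth_sigma_bins, mode="reflect")
    res = gpr_decode(emb.coords, y_smooth, seed=seed)
    res.target = "peer-neuron"
    res.n_units = len(ids) - 1
    return res


def decode_all_peer_neurons(binned: BinnedActivity, seed: int = 0, **kwargs) -> DecodingResult:
    """Average peer-neuron decoding over every non-silent target unit."""
    accs = []
    for uid in binned.unit_ids:
        try:
            accs.append(decode_peer_neuron(binned, uid, seed=seed, **kwargs).accuracy)
        except ValueError:
            continue
    return DecodingResult(
        target="peer-neuron", accuracy=float(np.mean(accs)), fold_accuracies=accs,
        n_units=binned.n_units, seed=seed,
    )
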