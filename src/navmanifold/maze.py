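"""T-maze geometry and linearized-position coordinates.

The alternation task runs in a 118 cm x 118 cm arena containing a start box
(30 cm x 10 cm), a central stem (10 cm wide) and left/right arms.  After
reward the animal returns to the start box along the outer wall, so one
trial traces a closed loop and the two turn directions together trace a
figure-8.

Positions along a trial are summarized by a linearized coordinate
``u in [0, 1]`` measured along the turn-specific loop.  The mapping from
arc length to ``u`` is piecewise linear and anchored at behavioral
landmarks so that the start box occupies u in [0.02, 0.08], the junction
(choice point) u in [0.55, 0.62], the arm u in [0.62, 0.86] and the reward
zone u in [0.86, 0.90]; the return leg fills (0.90, 1.0].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARENA_CM = 118.0

# landmark windows on the linearized coordinate
BOX_U = (0.02, 0.08)
CHOICE_U = (0.55, 0.62)
ARM_U = (0.62, 0.86)
REWARD_U = (0.86, 0.90)


def _right_waypoints() -> np.ndarray:
    # loop for a right-turn trial; left is the mirror image in x
    return np.array(
        [
            [59.0, 7.0],    # rear of start box
            [59.0, 32.0],   # box exit
            [59.0, 100.0],  # top of stem / junction
            [69.0, 100.0],  # end of choice zone
            [99.0, 100.0],  # arm
            [109.0, 100.0], # reward platform at arm end
            [109.0, 7.0],   # outer-wall return, bottom corner
            [59.0, 7.0],    # back to the box
        ]
    )


# u value assigned to each waypoint above (piecewise linear in between)
_WAYPOINT_U = np.array([0.0, 0.08, 0.55, 0.62, 0.86, 0.90, 0.97, 1.0])

BOX_HOLD_XY = (59.0, 17.0)  # where the rat sits during the start-box hold
BOX_HOLD_U = 0.08 * (17.0 - 7.0) / 25.0  # = 0.032, inside BOX_U


@dataclass(frozen=True)
class TMazeGeometry:
    """Closed figure-8 loop with a turn-specific linearized coordinate."""

    arena_cm: float = ARENA_CM
    waypoints_r: np.ndarray = field(default_factory=_right_waypoints)
    waypoint_u: np.ndarray = field(default_factory=lambda: _WAYPOINT_U.copy())

    def waypoints(self, turn: str) -> np.ndarray:
        w = self.waypoints_r.copy()
        if turn == "L":
            w[:, 0] = self.arena_cm - w[:, 0]
        elif turn != "R":
            raise ValueError(f"unknown turn {turn!r}")
        return w

    def _segments(self, turn: str):
        w = self.waypoints(turn)
        seg_vec = np.diff(w, axis=0)
        seg_len = np.linalg.norm(seg_vec, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        return w, seg_vec, seg_len, cum

    def total_length(self, turn: str = "R") -> float:
        return float(self._segments(turn)[3][-1])

    def point_at_arclength(self, s, turn: str):
        """(x, y) and tangent direction at arc length ``s`` along the loop."""
        w, seg_vec, seg_len, cum = self._segments(turn)
        s = np.atleast_1d(np.asarray(s, dtype=float)) % cum[-1]
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
        frac = (s - cum[idx]) / seg_len[idx]
        xy = w[idx] + seg_vec[idx] * frac[:, None]
        tangent = seg_vec[idx] / seg_len[idx][:, None]
        return xy, tangent

    def u_at_arclength(self, s, turn: str = "R"):
        """Landmark-anchored linearized coordinate at arc length ``s``."""
        cum = self._segments(turn)[3]
        s = np.atleast_1d(np.asarray(s, dtype=float)) % cum[-1]
        return np.interp(s, cum, self.waypoint_u)

    def linearize(self, x, y, turn: str):
        """Project points onto the loop; return (u, distance to path)."""
        w, seg_vec, seg_len, cum = self._segments(turn)
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]).astype(float)
        # projection onto every segment, keep the nearest
        rel = pts[:, None, :] - w[None, :-1, :]             # (n, m, 2)
        t = np.einsum("nmk,mk->nm", rel, seg_vec) / (seg_len**2)[None, :]
        t = np.clip(t, 0.0, 1.0)
        proj = w[None, :-1, :] + t[..., None] * seg_vec[None, :, :]
        d = np.linalg.norm(pts[:, None, :] - proj, axis=2)
        best = np.argmin(d, axis=1)
        n = np.arange(len(pts))
        s = cum[best] + t[n, best] * seg_len[best]
        return np.interp(s, cum, self.waypoint_u), d[n, best]


def landmark_of_u(u) -> np.ndarray:
    """Map linearized positions to landmark labels (box/choice/arm/reward/other)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.full(u.shape, "other", dtype=object)
    for name, (lo, hi) in [
        ("box", BOX_U),
        ("choice", CHOICE_U),
        ("arm", ARM_U),
        ("reward", REWARD_U),
    ]:
        out[(u >= lo) & (u < hi)] = name
    return out
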