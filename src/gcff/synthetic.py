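"""Synthetic conversational-scene generator and proxemic noise model.

Scenes are built from the four canonical F-formation arrangements —
vis-a-vis (two people facing each other), L-shape (two people at a
right angle), side-by-side (two people facing the same way) and
circular (any cardinality, members on a circle facing its centre) —
plus non-member singletons oriented away from every group.  Group
members are placed so their transactional-segment centres coincide at
the group's o-space centre (side-by-side: within half a stride), and
group centres are kept well separated so the ground truth is
unambiguous.

The default archetype batch emulates a hand-authored benchmark of 10
diverse social situations, each repeated 10 times with positional
jitter, averaging 9 individuals and 3 groups per frame.

The noise model perturbs each person's state independently with
additive zero-mean Gaussians whose standard deviations scale linearly
with an integer noise level L: x += N(0, (L*sigma_x)^2) and likewise
for y and theta.  N(0, s) is read as mean 0 and *standard deviation*
s, so the levels scale the spread linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .core import GroupSet, PersonState, Scene

__all__ = [
    "Arrangement",
    "SceneSpec",
    "NoiseSpec",
    "PlacementError",
    "generate_scene",
    "generate_batch",
    "add_noise",
    "ARCHETYPES",
]

Arrangement = Literal["vis_a_vis", "l_shape", "side_by_side", "circular"]

_PAIR_ONLY = {"vis_a_vis", "l_shape", "side_by_side"}


class PlacementError(RuntimeError):
    """Raised when the floor cannot accommodate the requested layout."""


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic frame.

    ``groups`` lists (arrangement, cardinality) pairs; pair
    arrangements (vis-a-vis, L-shape, side-by-side) imply cardinality
    2, circular allows any cardinality >= 2.  ``min_group_separation``
    must exceed 4 strides so ground truth stays unambiguous.  Lengths
    are centimetres by default.
    """

    groups: tuple[tuple[str, int], ...] = ()
    n_singletons: int = 0
    floor: tuple[float, float] = (1000.0, 800.0)
    min_group_separation: float = 180.0
    stride_D: float = 30.0
    seed: int = 0
    side_by_side_gap: float | None = None  # default: stride_D / 2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "groups", tuple((str(a), int(k)) for a, k in self.groups)
        )
        for arrangement, k in self.groups:
            if k < 2:
                raise ValueError("group cardinality must be >= 2")
            if arrangement in _PAIR_ONLY and k != 2:
                raise ValueError(f"{arrangement} arrangement implies cardinality 2")
            if arrangement not in _PAIR_ONLY and arrangement != "circular":
                raise ValueError(f"unknown arrangement {arrangement!r}")
        if self.n_singletons < 0:
            raise ValueError("n_singletons must be >= 0")
        if not self.min_group_separation > 4.0 * self.stride_D:
            raise ValueError("min_group_separation must exceed 4 * stride_D")

    @property
    def gap(self) -> float:
        return (
            self.stride_D / 2.0
            if self.side_by_side_gap is None
            else self.side_by_side_gap
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian proxemic noise at integer level ``level``.

    Defaults follow the customary calibration for centimetre scenes:
    sigma_x = sigma_y = 20 cm, sigma_theta = 0.1 rad, with 11 levels
    0..10 scaling the standard deviations linearly.
    """

    level: int = 0
    sigma_x: float = 20.0
    sigma_y: float = 20.0
    sigma_theta: float = 0.1
    seed: int = 0
    mode: Literal["both", "position", "orientation"] = "both"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be >= 0")
        if min(self.sigma_x, self.sigma_y, self.sigma_theta) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.mode not in ("both", "position", "orientation"):
            raise ValueError(f"unknown noise mode {self.mode!r}")


def _group_members(
    arrangement: str,
    k: int,
    centre: np.ndarray,
    phase: float,
    D: float,
    gap: float,
    start_id: int,
) -> list[PersonState]:
    """Members of one group, TS centres (nearly) coincident at ``centre``."""
    out = []
    if arrangement == "vis_a_vis":
        offsets = [phase, phase + math.pi]
    elif arrangement == "l_shape":
        offsets = [phase, phase + math.pi / 2]
    elif arrangement == "circular":
        offsets = [phase + 2.0 * math.pi * i / k for i in range(k)]
    else:  # side_by_side: both face direction `phase`
        perp = np.array([-math.sin(phase), math.cos(phase)])
        facing = np.array([math.cos(phase), math.sin(phase)])
        for i, side in enumerate((-0.5, 0.5)):
            pos = centre - D * facing + side * gap * perp
            out.append(
                PersonState(start_id + i, float(pos[0]), float(pos[1]), phase)
            )
        return out
    for i, ang in enumerate(offsets):
        pos = centre + D * np.array([math.cos(ang), math.sin(ang)])
        out.append(
            PersonState(
                start_id + i, float(pos[0]), float(pos[1]), ang + math.pi
            )
        )
    return out


def generate_scene(spec: SceneSpec, max_retries: int = 1000) -> Scene:
    """Generate one frame with ground truth from a scene recipe.

    Group o-space centres are placed uniformly at random on the floor,
    pairwise at least ``min_group_separation`` apart; each group's
    member layout is rotated by a random phase.  Singletons keep the
    same separation from every group centre *and* from each other's
    transactional-segment centres, and face away from the groups, so a
    correct detector has no legitimate reason to group them.

    Deterministic given the spec (the seed is part of it).  Raises
    :class:`PlacementError` when rejection sampling exhausts
    ``max_retries`` for any placement.
    """
    rng = np.random.default_rng(spec.seed)
    W, H = spec.floor
    margin = 2.0 * spec.stride_D
    sep = spec.min_group_separation

    def sample_point() -> np.ndarray:
        return np.array(
            [rng.uniform(margin, W - margin), rng.uniform(margin, H - margin)]
        )

    centres: list[np.ndarray] = []
    for _ in spec.groups:
        for attempt in range(max_retries + 1):
            c = sample_point()
            if all(np.hypot(*(c - o)) >= sep for o in centres):
                centres.append(c)
                break
        else:
            raise PlacementError(
                f"could not place {len(spec.groups)} group centres at "
                f"separation {sep} on floor {spec.floor}"
            )

    persons: list[PersonState] = []
    groups: list[frozenset] = []
    next_id = 0
    for (arrangement, k), centre in zip(spec.groups, centres):
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        members = _group_members(
            arrangement, k, centre, phase, spec.stride_D, spec.gap, next_id
        )
        persons.extend(members)
        groups.append(frozenset(p.id for p in members))
        next_id += len(members)

    single_ts: list[np.ndarray] = []
    singleton_ids: list[int] = []
    for _ in range(spec.n_singletons):
        for attempt in range(max_retries + 1):
            pos = sample_point()
            if any(np.hypot(*(pos - c)) < sep for c in centres):
                continue
            if centres:
                away = sum(
                    (pos - c) / max(np.hypot(*(pos - c)), 1e-9) for c in centres
                )
                if np.hypot(*away) < 1e-9:
                    theta = float(rng.uniform(-math.pi, math.pi))
                else:
                    theta = math.atan2(away[1], away[0])
            else:
                theta = float(rng.uniform(-math.pi, math.pi))
            ts = pos + spec.stride_D * np.array([math.cos(theta), math.sin(theta)])
            if any(np.hypot(*(ts - other)) < sep for other in single_ts):
                continue
            persons.append(PersonState(next_id, float(pos[0]), float(pos[1]), theta))
            singleton_ids.append(next_id)
            single_ts.append(ts)
            next_id += 1
            break
        else:
            raise PlacementError(
                f"could not place {spec.n_singletons} singletons on floor "
                f"{spec.floor} at separation {sep}"
            )

    truth = GroupSet(groups=tuple(groups), singletons=frozenset(singleton_ids))
    return Scene(persons=tuple(persons), truth=truth, unit="cm")


# Ten archetype layouts: 90 persons and 30 groups in total, i.e. an
# average of 9 individuals and 3 groups per frame, mixing all four
# arrangements and cardinalities 2-6 with non-member singletons.
ARCHETYPES: tuple[SceneSpec, ...] = tuple(
    SceneSpec(groups=g, n_singletons=s)
    for g, s in [
        ((("vis_a_vis", 2), ("l_shape", 2), ("side_by_side", 2)), 2),
        ((("circular", 3), ("vis_a_vis", 2), ("vis_a_vis", 2)), 1),
        ((("circular", 4), ("l_shape", 2), ("side_by_side", 2)), 1),
        ((("circular", 5), ("circular", 3)), 1),
        ((("circular", 6), ("vis_a_vis", 2), ("l_shape", 2)), 0),
        ((("vis_a_vis", 2), ("vis_a_vis", 2), ("l_shape", 2), ("side_by_side", 2)), 1),
        ((("circular", 3), ("circular", 3), ("vis_a_vis", 2)), 0),
        ((("circular", 4), ("circular", 3), ("side_by_side", 2)), 1),
        ((("circular", 5), ("l_shape", 2)), 2),
        ((("circular", 3), ("vis_a_vis", 2), ("side_by_side", 2), ("l_shape", 2)), 1),
    ]
)


def generate_batch(
    seed: int = 0,
    n_repeats: int = 10,
    archetypes: Sequence[SceneSpec] = ARCHETYPES,
) -> list[Scene]:
    """The default benchmark batch: each archetype repeated with jitter.

    Every repeat re-seeds the layout, so placements and phases vary
    while the group structure of each archetype is preserved.  With
    the default 10 archetypes x 10 repeats this yields 100 frames.
    """
    scenes = []
    for rep in range(n_repeats):
        for a_idx, arch in enumerate(archetypes):
            scenes.append(
                generate_scene(
                    replace(arch, seed=seed * 1_000_003 + rep * 101 + a_idx)
                )
            )
    return scenes


def add_noise(scene: Scene, noise: NoiseSpec) -> Scene:
    """Perturb every person's state with level-scaled Gaussian noise.

    Position and/or orientation (per ``noise.mode``) receive additive
    N(0, (level*sigma)^2) draws, independently per person and axis.
    Ground truth and unit metadata are unchanged; level 0 returns an
    identical scene.  Deterministic given ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    n = len(scene)
    # always draw all three blocks so position-only and combined runs
    # with one seed share the same positional draws
    dx = rng.normal(0.0, 1.0, n)
    dy = rng.normal(0.0, 1.0, n)
    dth = rng.normal(0.0, 1.0, n)
    L = float(noise.level)
    use_pos = noise.mode in ("both", "position") and L > 0
    use_ori = noise.mode in ("both", "orientation") and L > 0
    persons = tuple(
        PersonState(
            p.id,
            p.x + L * noise.sigma_x * dx[i] if use_pos else p.x,
            p.y + L * noise.sigma_y * dy[i] if use_pos else p.y,
            p.theta + L * noise.sigma_theta * dth[i] if use_ori else p.theta,
        )
        for i, p in enumerate(scene)
    )
    return Scene(persons=persons, truth=scene.truth, unit=scene.unit)
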