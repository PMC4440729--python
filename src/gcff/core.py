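"""Domain types and energy terms for F-formation detection.

An F-formation is the socio-spatial arrangement people adopt in a
free-standing conversation: participants surround a shared, convex,
empty *o-space* into which everyone orients.  Each person's
*transactional segment* — the region in front of the body where sight
and hearing are most effective — is modelled as an isotropic Gaussian
centred one stride ``D`` ahead of the person along their facing
direction.  People belong to the same group when their transactional
segments overlap on a common o-space centre.

The objective minimised over candidate o-space centres is a
least-squares data term (squared distance from each person's
transactional-segment centre to their group's o-space centre) plus a
minimum-description-length (MDL) penalty of ``sigma**2`` per group,
optionally extended with a visibility term that penalises joining a
group whose centre is occluded by a nearer person.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PersonState",
    "Scene",
    "GroupSet",
    "TSCentre",
    "OSpaceCentre",
    "ModelParams",
    "Assignment",
    "InvalidInputError",
    "DegenerateGeometryError",
    "InconsistentAssignmentError",
    "normalize_angle",
    "ts_centre",
    "unary_cost",
    "visibility_cost",
    "person_visibility_penalty",
    "scene_cost",
]


class InvalidInputError(ValueError):
    """Raised for non-finite coordinates or malformed domain objects."""


class DegenerateGeometryError(ValueError):
    """Raised when an o-space centre coincides with an occluding person."""


class InconsistentAssignmentError(ValueError):
    """Raised when an assignment references a label without a centre."""


def normalize_angle(theta: float) -> float:
    """Wrap an angle in radians to the half-open interval (-pi, pi]."""
    if not math.isfinite(theta):
        raise InvalidInputError(f"non-finite angle: {theta!r}")
    wrapped = math.remainder(theta, 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class PersonState:
    """One individual's proxemic state within a frame.

    Parameters
    ----------
    id : hashable
        Identifier, unique within a scene.
    x, y : float
        Ground-plane position, in the scene's length unit (cm or px).
    theta : float
        Head orientation in radians, counter-clockwise from the +x axis.
        Normalised to (-pi, pi] on construction.
    """

    id: Hashable
    x: float
    y: float
    theta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError(
                f"person {self.id!r} has non-finite position ({self.x}, {self.y})"
            )
        object.__setattr__(self, "theta", normalize_angle(self.theta))

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class TSCentre:
    """Centre of a person's transactional segment: one stride ahead."""

    u: float
    v: float

    @property
    def array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass(frozen=True)
class OSpaceCentre:
    """A candidate o-space centre carrying its group label."""

    u: float
    v: float
    label: Hashable = None

    @property
    def array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass(frozen=True)
class GroupSet:
    """A partition of a frame's person ids into groups and singletons.

    ``groups`` holds the conversational groups (cardinality >= 2);
    lone individuals — spurious one-member F-formations in the model —
    are reported separately in ``singletons``.
    """

    groups: tuple[frozenset, ...] = ()
    singletons: frozenset = frozenset()

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "singletons", frozenset(self.singletons))
        seen: set = set()
        for g in groups:
            if len(g) < 2:
                raise InvalidInputError("groups must have cardinality >= 2")
            if seen & g:
                raise InvalidInputError("person appears in more than one group")
            seen |= g
        if seen & self.singletons:
            raise InvalidInputError("person is both grouped and singleton")

    @property
    def all_ids(self) -> frozenset:
        ids: set = set(self.singletons)
        for g in self.groups:
            ids |= g
        return frozenset(ids)

    def as_lists(self) -> list[list]:
        """Groups as sorted lists of ids (stable, JSON-friendly)."""
        return sorted(
            (sorted(g, key=repr) for g in self.groups),
            key=lambda g: [repr(i) for i in g],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroupSet):
            return NotImplemented
        return (
            set(self.groups) == set(other.groups)
            and self.singletons == other.singletons
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.groups), self.singletons))


@dataclass(frozen=True)
class Scene:
    """A single frame: the people in it, plus optional ground truth.

    Person ids must be unique.  ``unit`` is metadata only ("cm" or
    "px"); all computations are unit-agnostic as long as positions,
    stride and sigma share the unit.
    """

    persons: tuple[PersonState, ...]
    truth: GroupSet | None = None
    unit: str = "cm"

    def __post_init__(self) -> None:
        persons = tuple(self.persons)
        object.__setattr__(self, "persons", persons)
        ids = [p.id for p in persons]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate person ids in scene")
        if self.truth is not None and not self.truth.all_ids <= set(ids):
            raise InvalidInputError("ground truth references unknown person ids")

    def __len__(self) -> int:
        return len(self.persons)

    def __iter__(self):
        return iter(self.persons)

    @property
    def ids(self) -> list:
        return [p.id for p in self.persons]

    def positions(self) -> np.ndarray:
        """(n, 2) array of ground-plane positions."""
        return np.array([[p.x, p.y] for p in self.persons], dtype=float).reshape(-1, 2)

    def thetas(self) -> np.ndarray:
        return np.array([p.theta for p in self.persons], dtype=float)

    def ts_centres(self, D: float) -> np.ndarray:
        """(n, 2) array of transactional-segment centres at stride D."""
        pos = self.positions()
        th = self.thetas()
        return pos + D * np.column_stack([np.cos(th), np.sin(th)])


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the detection energy.

    Attributes
    ----------
    stride_D : float
        Distance from a person to their transactional-segment centre,
        in scene units.  Circular groups are assumed to have diameter
        ~2*D, so D encodes the social context (and the unit).
    sigma : float
        Scale of acceptable deviation from the shared o-space centre.
        Also sets the MDL per-group penalty (``mdl_weight = sigma**2``
        unless overridden), so larger sigma both tolerates looser
        groups and merges more aggressively.
    vis_theta_hat : float
        Angular half-width (radians) of the occlusion window: person j
        occludes person i's view of a centre only when the angle they
        subtend at the centre is below this threshold.
    vis_K : float
        Gain of the angular occlusion term exp(K*cos(theta)).
    use_visibility : bool
        Include the occlusion penalty in the energy.
    mdl_weight : float or None
        Per-group penalty; defaults to sigma**2.
    max_iters, cost_tol : int, float
        Convergence controls of the alternating descent.
    """

    stride_D: float = 30.0
    sigma: float = 80.0
    vis_theta_hat: float = math.pi / 6
    vis_K: float = 1.0
    use_visibility: bool = True
    mdl_weight: float | None = None
    max_iters: int = 100
    cost_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.stride_D > 0:
            raise InvalidInputError("stride_D must be > 0")
        if not self.sigma > 0:
            raise InvalidInputError("sigma must be > 0")
        if self.vis_K < 0:
            raise InvalidInputError("vis_K must be >= 0")
        if not 0 <= self.vis_theta_hat <= math.pi:
            raise InvalidInputError("vis_theta_hat must lie in [0, pi]")

    @property
    def label_cost(self) -> float:
        """Effective MDL penalty per used o-space centre."""
        return self.sigma**2 if self.mdl_weight is None else self.mdl_weight


@dataclass
class Assignment:
    """Working state of the optimiser: who belongs to which centre.

    ``labels`` maps every person id to a label, ``centres`` maps every
    used label to its o-space centre, and ``energy`` caches the value
    of the objective for this state.
    """

    labels: dict = field(default_factory=dict)
    centres: dict = field(default_factory=dict)
    energy: float = 0.0

    def groups(self) -> GroupSet:
        """Collapse to a GroupSet: multi-member labels vs singletons."""
        members: dict = {}
        for pid, lab in self.labels.items():
            members.setdefault(lab, set()).add(pid)
        groups = [frozenset(m) for m in members.values() if len(m) >= 2]
        singles = frozenset(
            next(iter(m)) for m in members.values() if len(m) == 1
        )
        return GroupSet(groups=tuple(groups), singletons=singles)


# ---------------------------------------------------------------------------
# Energy terms


def ts_centre(p: PersonState, D: float) -> TSCentre:
    """Transactional-segment centre: one stride ahead of the person.

    Returns the point ``(x + D cos(theta), y + D sin(theta))``.
    """
    if not D > 0:
        raise InvalidInputError("stride D must be > 0")
    return TSCentre(p.x + D * math.cos(p.theta), p.y + D * math.sin(p.theta))


def unary_cost(p: PersonState, centre: OSpaceCentre, params: ModelParams) -> float:
    """Squared distance from the person's TS centre to an o-space centre."""
    mu = ts_centre(p, params.stride_D)
    return (centre.u - mu.u) ** 2 + (centre.v - mu.v) ** 2


def visibility_cost(
    i: PersonState, j: PersonState, centre: OSpaceCentre, params: ModelParams
) -> float:
    """Occlusion penalty on person ``i`` by person ``j`` for a centre.

    Zero when ``i`` is at least as close to the centre as ``j``, or when
    the angle the two subtend at the centre is at least the occlusion
    threshold (they are angularly well separated).  Otherwise ``j``
    stands between ``i`` and the centre and the penalty is
    ``exp(K cos(theta_ij)) * (d_i - d_j) / d_j``.
    """
    ci = np.array([i.x - centre.u, i.y - centre.v])
    cj = np.array([j.x - centre.u, j.y - centre.v])
    di = float(np.hypot(*ci))
    dj = float(np.hypot(*cj))
    if di <= dj:  # ties count as "closer": no occlusion
        return 0.0
    if dj == 0.0:
        raise DegenerateGeometryError(
            f"o-space centre coincides with occluding person {j.id!r}"
        )
    cos_t = float(np.dot(ci, cj)) / (di * dj)
    cos_t = min(1.0, max(-1.0, cos_t))
    theta_ij = math.acos(cos_t)
    if theta_ij >= params.vis_theta_hat:
        return 0.0
    return math.exp(params.vis_K * cos_t) * (di - dj) / dj


def person_visibility_penalty(
    i: PersonState, scene: Scene, centre: OSpaceCentre, params: ModelParams
) -> float:
    """Total occlusion penalty on ``i`` for a candidate centre.

    Sums ``visibility_cost(i, j, centre)`` over every other person in
    the scene, regardless of which group ``j`` belongs to — the term
    depends only on ``i`` and the centre, so it acts as a unary cost.
    """
    return sum(
        visibility_cost(i, j, centre, params) for j in scene if j.id != i.id
    )


def scene_cost(scene: Scene, assignment: Assignment, params: ModelParams) -> float:
    """Total energy of an assignment: data + MDL + visibility terms.

    ``sum_i ||mu_i - O_{G_i}||^2 + mdl_weight * #labels
    + sum_i sum_{j != i} R_{i,j}(O_{G_i})``
    (the visibility sum only when ``params.use_visibility``).
    """
    used: set = set()
    total = 0.0
    for p in scene:
        if p.id not in assignment.labels:
            raise InconsistentAssignmentError(f"person {p.id!r} has no label")
        lab = assignment.labels[p.id]
        if lab not in assignment.centres:
            raise InconsistentAssignmentError(
                f"label {lab!r} of person {p.id!r} has no centre"
            )
        centre = assignment.centres[lab]
        used.add(lab)
        total += unary_cost(p, centre, params)
        if params.use_visibility:
            total += person_visibility_penalty(p, scene, centre, params)
    return total + params.label_cost * len(used)


def transform_scene(
    scene: Scene,
    rotation: float = 0.0,
    translation: Sequence[float] = (0.0, 0.0),
    scale: float = 1.0,
) -> Scene:
    """Apply a similarity transform (rotate, scale, then translate).

    Utility for equivariance checks and unit conversion; ground truth
    is carried over unchanged.
    """
    c, s = math.cos(rotation), math.sin(rotation)
    tx, ty = translation
    persons = tuple(
        PersonState(
            p.id,
            scale * (c * p.x - s * p.y) + tx,
            scale * (s * p.x + c * p.y) + ty,
            p.theta + rotation,
        )
        for p in scene
    )
    return Scene(persons=persons, truth=scene.truth, unit=scene.unit)
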