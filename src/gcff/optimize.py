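"""Alternating minimisation of the group-detection energy.

The objective has uncapacitated-facility-location structure: given a
set of candidate o-space centres, every person term (data + occlusion)
is unary in the person's own centre, and each *used* centre pays a
flat MDL cost.  The assignment step therefore reduces to choosing the
subset of candidates that minimises

    sum_i  min_{k in S} cost(i, k)  +  label_cost * |S|

which this module solves exactly by vectorised subset enumeration for
small candidate sets and by greedy drop/add/swap local search for
larger ones.  The outer loop alternates assignment with centre updates
(the mean of member transactional-segment centres), passing the
previous centres along as proposals so the energy can never increase,
plus pooled-mean merge proposals for nearby groups so that profitable
merges are found even when neither group's current centre is a good
shared centre.  Descent is monotone and the iteration count finite, so
convergence is guaranteed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    Assignment,
    GroupSet,
    ModelParams,
    OSpaceCentre,
    Scene,
)

__all__ = ["SolverTrace", "assign_labels", "update_centres", "gcff_detect"]

# Largest candidate count solved by exact enumeration (2^m subsets).
MAX_EXACT_CANDIDATES = 16

# Penalty used when a candidate centre coincides with an occluding
# person (the exact cost diverges); effectively forbids the assignment.
_OCCLUDED_BY_COINCIDENT = 1e12


@dataclass(frozen=True)
class SolverTrace:
    """Energy trajectory of the alternating descent."""

    iterations: int
    energies: tuple[float, ...]
    converged: bool


# ---------------------------------------------------------------------------
# Vectorised cost matrix


def _visibility_matrix(pos: np.ndarray, cand: np.ndarray, params: ModelParams) -> np.ndarray:
    """(n, m) matrix of per-person occlusion penalties per candidate."""
    n = pos.shape[0]
    m = cand.shape[0]
    V = np.zeros((n, m))
    if n < 2 or params.vis_theta_hat == 0.0:
        return V
    cos_hat = math.cos(params.vis_theta_hat)
    for k in range(m):
        diff = pos - cand[k]  # (n, 2)
        d = np.hypot(diff[:, 0], diff[:, 1])  # (n,)
        with np.errstate(divide="ignore", invalid="ignore"):
            cos_t = (diff @ diff.T) / np.outer(d, d)
        np.clip(cos_t, -1.0, 1.0, out=cos_t)
        # i occluded by j: i strictly farther and angular gap below the
        # window (cos above its cosine).
        farther = d[:, None] > d[None, :]
        occluded = farther & (cos_t > cos_hat)
        np.fill_diagonal(occluded, False)
        with np.errstate(divide="ignore", invalid="ignore"):
            pen = np.exp(params.vis_K * cos_t) * (d[:, None] - d[None, :]) / d[None, :]
        pen = np.where(occluded, pen, 0.0)
        # centre exactly on an occluder: diverging cost, large finite stand-in
        coincident = (d[None, :] == 0.0) & farther
        np.fill_diagonal(coincident, False)
        pen = np.where(coincident, _OCCLUDED_BY_COINCIDENT, pen)
        V[:, k] = np.nansum(pen, axis=1)
    return V


def _cost_matrix(scene: Scene, cand: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-person, per-candidate unary cost (data + occlusion terms)."""
    mu = scene.ts_centres(params.stride_D)  # (n, 2)
    diff = mu[:, None, :] - cand[None, :, :]
    A = np.einsum("nmk,nmk->nm", diff, diff)
    if params.use_visibility:
        A = A + _visibility_matrix(scene.positions(), cand, params)
    return A


# ---------------------------------------------------------------------------
# Subset solvers


def _popcount(masks: np.ndarray) -> np.ndarray:
    try:
        return np.bitwise_count(masks)
    except AttributeError:  # pragma: no cover - numpy < 2.0
        return np.array([bin(int(v)).count("1") for v in masks])


def _solve_exact(A: np.ndarray, w: float) -> tuple[np.ndarray, float]:
    """Exact minimum over all non-empty candidate subsets.

    Ties in total cost prefer the subset with more open centres (so a
    merge must be strictly profitable), then the smaller bitmask.
    """
    n, m = A.shape
    masks = np.arange(1, 2**m, dtype=np.uint64)
    best = np.full((masks.size, n), np.inf)
    for k in range(m):
        sel = (masks >> np.uint64(k)) & np.uint64(1) == 1
        best[sel] = np.minimum(best[sel], A[:, k])
    counts = _popcount(masks).astype(np.int64)
    totals = best.sum(axis=1) + w * counts
    order = np.lexsort((masks, -counts, totals))
    mask = int(masks[order[0]])
    open_idx = np.flatnonzero([(mask >> k) & 1 for k in range(m)])
    sub = A[:, open_idx]
    choice = open_idx[np.argmin(sub, axis=1)]  # first min -> lowest label id
    energy = float(sub.min(axis=1).sum() + w * len(open_idx))
    return choice, energy


def _subset_cost(A: np.ndarray, w: float, open_: Sequence[int]) -> float:
    idx = np.fromiter(open_, dtype=int)
    return float(A[:, idx].min(axis=1).sum() + w * idx.size)


def _solve_local(A: np.ndarray, w: float, warm: Sequence[int] | None) -> tuple[np.ndarray, float]:
    """Greedy drop/add/swap local search over candidate subsets."""
    n, m = A.shape
    starts = [set(range(m))]
    if warm:
        starts.append(set(warm))
    best_choice, best_energy = None, np.inf
    for open_ in starts:
        cost = _subset_cost(A, w, open_)
        improved = True
        while improved:
            improved = False
            for k in sorted(open_):
                if len(open_) == 1:
                    break
                c = _subset_cost(A, w, open_ - {k})
                if c < cost - 1e-12:
                    open_.remove(k)
                    cost = c
                    improved = True
            for k in range(m):
                if k in open_:
                    continue
                c = _subset_cost(A, w, open_ | {k})
                if c < cost - 1e-12:
                    open_.add(k)
                    cost = c
                    improved = True
            for k_in in range(m):
                if k_in in open_:
                    continue
                for k_out in sorted(open_):
                    trial = (open_ - {k_out}) | {k_in}
                    c = _subset_cost(A, w, trial)
                    if c < cost - 1e-12:
                        open_ = trial
                        cost = c
                        improved = True
                        break
        if cost < best_energy:
            idx = np.array(sorted(open_))
            sub = A[:, idx]
            choice = idx[np.argmin(sub, axis=1)]
            # unused open centres only add label cost: prune them
            used = sorted(set(choice.tolist()))
            sub = A[:, used]
            best_choice = np.array(used)[np.argmin(sub, axis=1)]
            best_energy = float(sub.min(axis=1).sum() + w * len(used))
    return best_choice, best_energy


def _as_array(candidates) -> np.ndarray:
    if isinstance(candidates, np.ndarray):
        return candidates.reshape(-1, 2).astype(float)
    return np.array(
        [[c.u, c.v] if isinstance(c, OSpaceCentre) else list(c) for c in candidates],
        dtype=float,
    ).reshape(-1, 2)


def _assign(
    scene: Scene,
    cand: np.ndarray,
    params: ModelParams,
    warm: Sequence[int] | None = None,
) -> tuple[Assignment, np.ndarray]:
    """Solve the assignment step; returns the Assignment and the raw
    per-person candidate choice (indices into ``cand``)."""
    if len(scene) == 0:
        return Assignment(labels={}, centres={}, energy=0.0), np.empty(0, int)
    A = _cost_matrix(scene, cand, params)
    w = params.label_cost
    if cand.shape[0] <= MAX_EXACT_CANDIDATES:
        choice, energy = _solve_exact(A, w)
    else:
        choice, energy = _solve_local(A, w, warm)
    used = sorted(set(choice.tolist()))
    relabel = {k: g for g, k in enumerate(used)}
    labels = {p.id: relabel[int(choice[i])] for i, p in enumerate(scene)}
    centres = {
        relabel[k]: OSpaceCentre(float(cand[k, 0]), float(cand[k, 1]), label=relabel[k])
        for k in used
    }
    return Assignment(labels=labels, centres=centres, energy=energy), choice


def assign_labels(scene: Scene, candidates, params: ModelParams) -> Assignment:
    """Assign every person to one of the candidate o-space centres.

    Minimises the sum of per-person costs plus ``label_cost`` per used
    candidate, over all non-empty candidate subsets; each person takes
    their cheapest open centre (ties to the lowest label id).  Labels
    in the returned assignment are re-indexed 0..g-1 in candidate
    order.  An empty scene yields an empty assignment with energy 0.
    """
    cand = _as_array(candidates)
    if len(scene) > 0 and cand.shape[0] == 0:
        raise ValueError("no candidate centres supplied")
    assignment, _ = _assign(scene, cand, params)
    return assignment


def update_centres(
    scene: Scene, assignment: Assignment, params: ModelParams
) -> list[OSpaceCentre]:
    """Re-centre every non-empty group at its members' mean TS centre.

    Emits one proposal per active label — the new mean — and, when the
    visibility term is active, additionally the label's previous
    centre, so a centre move that triggers a large occlusion penalty
    can be rejected by the next assignment step.  Labels with no
    members produce no proposal.
    """
    mu = scene.ts_centres(params.stride_D)
    members: dict = {}
    for i, p in enumerate(scene):
        lab = assignment.labels.get(p.id)
        if lab is not None:
            members.setdefault(lab, []).append(i)
    proposals: list[OSpaceCentre] = []
    for lab in sorted(members, key=repr):
        mean = mu[members[lab]].mean(axis=0)
        proposals.append(OSpaceCentre(float(mean[0]), float(mean[1]), label=lab))
        if params.use_visibility and lab in assignment.centres:
            prev = assignment.centres[lab]
            proposals.append(OSpaceCentre(prev.u, prev.v, label=lab))
    return proposals


def _merge_proposals(
    scene: Scene, assignment: Assignment, params: ModelParams, max_pairs: int = 20
) -> list[OSpaceCentre]:
    """Pooled-mean proposals for pairs of nearby active groups.

    Merging labels g and h is only ever profitable when their centres
    lie within a few sigma of each other (the saved label cost is
    sigma^2), so proposals are restricted to pairs closer than
    3*sigma, nearest first.
    """
    mu = scene.ts_centres(params.stride_D)
    members: dict = {}
    for i, p in enumerate(scene):
        members.setdefault(assignment.labels[p.id], []).append(i)
    labs = sorted(members, key=repr)
    if len(labs) < 2:
        return []
    centres = {lab: mu[members[lab]].mean(axis=0) for lab in labs}
    pairs = []
    for a in range(len(labs)):
        for b in range(a + 1, len(labs)):
            d = float(np.hypot(*(centres[labs[a]] - centres[labs[b]])))
            if d < 3.0 * params.sigma:
                pairs.append((d, labs[a], labs[b]))
    pairs.sort(key=lambda t: (t[0], repr(t[1]), repr(t[2])))
    out = []
    for _, ga, gb in pairs[:max_pairs]:
        pooled = mu[members[ga] + members[gb]].mean(axis=0)
        out.append(OSpaceCentre(float(pooled[0]), float(pooled[1])))
    return out


def _set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def _bipartitions(items: list):
    """All splits of ``items`` into two non-empty blocks, plus no split."""
    n = len(items)
    yield [items]
    for mask in range(1, 2 ** (n - 1)):
        a = [items[i] for i in range(n) if (mask >> i) & 1]
        b = [items[i] for i in range(n) if not (mask >> i) & 1]
        yield [a, b]


def _polish_partition(
    scene: Scene, blocks: list[tuple[int, ...]], params: ModelParams
) -> tuple[list[tuple[int, ...]], float, bool]:
    """Refine a partition by exact re-partition of blocks and block pairs.

    Coordinate descent over candidate centres can stall in labellings
    where, e.g., one group should split into two sub-pairs, or two
    groups should exchange members — moves that require opening several
    new centres at once.  This polish enumerates every re-partition of
    each single block and of each pair of blocks (centres at member TS
    means, the update rule's fixed point) and applies the best strict
    improvement until none exists.  Deterministic; energy strictly
    decreases with every accepted move.
    """
    mu = scene.ts_centres(params.stride_D)
    pos = scene.positions()
    w = params.label_cost
    cache: dict[tuple[int, ...], float] = {}

    def block_cost(block: tuple[int, ...]) -> float:
        if block not in cache:
            idx = list(block)
            centre = mu[idx].mean(axis=0)
            e = float(((mu[idx] - centre) ** 2).sum()) + w
            if params.use_visibility:
                e += float(
                    _visibility_matrix(pos, centre[None, :], params)[idx, 0].sum()
                )
            cache[block] = e
        return cache[block]

    def repartitions(union: list[int]):
        if len(union) <= 8:
            yield from _set_partitions(union)
        elif len(union) <= 14:
            yield from _bipartitions(union)
        else:
            yield [union]

    blocks = sorted(tuple(sorted(b)) for b in blocks)
    improved_any = False
    while True:
        best_delta = -1e-9
        best_move = None
        targets = [((a,), list(blocks[a])) for a in range(len(blocks)) if len(blocks[a]) >= 2]
        # pairs of blocks are only worth re-partitioning jointly when
        # they are close: single-member moves between far blocks are
        # already optimal under the unary assignment step
        centres = [mu[list(b)].mean(axis=0) for b in blocks]
        targets += [
            ((a, b), list(blocks[a]) + list(blocks[b]))
            for a in range(len(blocks))
            for b in range(a + 1, len(blocks))
            if float(np.hypot(*(centres[a] - centres[b]))) < 4.0 * params.sigma
        ]
        for which, union in targets:
            old = sum(block_cost(blocks[a]) for a in which)
            current = {blocks[a] for a in which}
            for part in repartitions(union):
                tpart = [tuple(sorted(p)) for p in part]
                if set(tpart) == current:
                    continue
                new = sum(block_cost(p) for p in tpart)
                if new - old < best_delta:
                    best_delta = new - old
                    best_move = (which, tpart)
        if best_move is None:
            break
        which, parts = best_move
        blocks = [b for a, b in enumerate(blocks) if a not in which] + parts
        blocks = sorted(blocks)
        improved_any = True
    energy = sum(block_cost(b) for b in blocks)
    return blocks, energy, improved_any


def gcff_detect(
    scene: Scene, params: ModelParams | None = None
) -> tuple[GroupSet, Assignment, SolverTrace]:
    """Detect conversational groups in a single frame.

    Starts from one candidate o-space centre per person (their own
    transactional-segment centre) and alternates between the exact
    assignment step and centre updates until the relative energy
    decrease falls below ``cost_tol`` or ``max_iters`` is reached.
    The converged labelling is then polished by exact re-partition of
    single groups and group pairs (see :func:`_polish_partition`); if
    the polish improves the energy, the alternation resumes from the
    refined labelling.  Deterministic: no randomness anywhere, fixed
    tie-breaks, monotone energy descent throughout.

    Returns the detected groups (labels with >= 2 members; the rest
    are singletons), the final assignment and the energy trace.
    """
    params = params or ModelParams()
    if len(scene) == 0:
        return GroupSet(), Assignment(), SolverTrace(0, (), True)
    cand = scene.ts_centres(params.stride_D)
    assignment, _ = _assign(scene, cand, params)
    energies = [assignment.energy]
    converged = False
    for _ in range(params.max_iters):
        # -- alternation step ------------------------------------------
        proposals = update_centres(scene, assignment, params)
        if not params.use_visibility:
            # keep the previous centres in play so the incumbent
            # labelling stays feasible and descent is monotone
            proposals += [
                assignment.centres[lab]
                for lab in sorted(assignment.centres, key=repr)
            ]
        proposals += _merge_proposals(scene, assignment, params)
        cand = np.unique(_as_array(proposals), axis=0)
        # rows holding the previous centres: keeping them feasible is
        # what guarantees monotone descent on the local-search path
        rows = {(cand[r, 0], cand[r, 1]): r for r in range(cand.shape[0])}
        warm = sorted(
            {
                rows[(c.u, c.v)]
                for c in assignment.centres.values()
                if (c.u, c.v) in rows
            }
        )
        new_assignment, _ = _assign(scene, cand, params, warm=warm or None)
        old_e, new_e = energies[-1], new_assignment.energy
        if new_e <= old_e:
            assignment = new_assignment
            if new_e < old_e:
                energies.append(new_e)
        if old_e - new_e > params.cost_tol * max(abs(old_e), 1.0):
            continue
        # -- converged: try the partition polish -----------------------
        index_of = {p.id: i for i, p in enumerate(scene)}
        members: dict = {}
        for pid, lab in assignment.labels.items():
            members.setdefault(lab, []).append(index_of[pid])
        blocks, energy, improved = _polish_partition(
            scene, [tuple(sorted(b)) for b in members.values()], params
        )
        if not improved or energy >= energies[-1]:
            converged = True
            break
        ids = scene.ids
        mu = scene.ts_centres(params.stride_D)
        assignment = Assignment(
            labels={ids[i]: lab for lab, block in enumerate(blocks) for i in block},
            centres={
                lab: OSpaceCentre(*mu[list(block)].mean(axis=0), label=lab)
                for lab, block in enumerate(blocks)
            },
            energy=energy,
        )
        energies.append(energy)
    trace = SolverTrace(
        iterations=len(energies) - 1,
        energies=tuple(energies),
        converged=converged,
    )
    return assignment.groups(), assignment, trace
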