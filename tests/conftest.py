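"""Shared fixtures and independent oracles for the test suite.

The oracles here recompute energies and matchings from first
principles (plain ``math``, exhaustive enumeration) so that they share
no code path with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from gcff import ModelParams, PersonState, Scene

DEFAULT_D = 30.0
DEFAULT_SIGMA = 80.0


@pytest.fixture
def params() -> ModelParams:
    return ModelParams(stride_D=DEFAULT_D, sigma=DEFAULT_SIGMA)


@pytest.fixture
def params_novis() -> ModelParams:
    return ModelParams(stride_D=DEFAULT_D, sigma=DEFAULT_SIGMA, use_visibility=False)


def make_random_scene(rng: np.random.Generator, n: int, extent: float = 300.0) -> Scene:
    persons = tuple(
        PersonState(
            i,
            float(rng.uniform(0.0, extent)),
            float(rng.uniform(0.0, extent)),
            float(rng.uniform(-math.pi, math.pi)),
        )
        for i in range(n)
    )
    return Scene(persons=persons)


# ---------------------------------------------------------------------------
# Independent energy oracle (scalar math only)


def oracle_ts(p: PersonState, D: float) -> tuple[float, float]:
    return (p.x + D * math.cos(p.theta), p.y + D * math.sin(p.theta))


def oracle_vis_penalty(
    scene: Scene, person: PersonState, centre: tuple[float, float], params: ModelParams
) -> float:
    """Hand-rolled occlusion penalty: sum over nearer, angularly close others."""
    cx, cy = centre
    di = math.hypot(person.x - cx, person.y - cy)
    total = 0.0
    for other in scene:
        if other.id == person.id:
            continue
        dj = math.hypot(other.x - cx, other.y - cy)
        if di <= dj:
            continue
        dot = (person.x - cx) * (other.x - cx) + (person.y - cy) * (other.y - cy)
        cos_t = max(-1.0, min(1.0, dot / (di * dj)))
        if math.acos(cos_t) >= params.vis_theta_hat:
            continue
        total += math.exp(params.vis_K * cos_t) * (di - dj) / dj
    return total


def oracle_partition_energy(scene: Scene, blocks: list[list], params: ModelParams) -> float:
    """Energy of a partition with centres at member TS means."""
    by_id = {p.id: p for p in scene}
    total = params.label_cost * len(blocks)
    for block in blocks:
        ts = [oracle_ts(by_id[i], params.stride_D) for i in block]
        cu = sum(t[0] for t in ts) / len(ts)
        cv = sum(t[1] for t in ts) / len(ts)
        for (tu, tv), pid in zip(ts, block):
            total += (tu - cu) ** 2 + (tv - cv) ** 2
            if params.use_visibility:
                total += oracle_vis_penalty(scene, by_id[pid], (cu, cv), params)
    return total


def set_partitions(items: list):
    """All set partitions (Bell-number many) of a list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def oracle_best_partition_energy(scene: Scene, params: ModelParams) -> float:
    """Exhaustive all-partitions minimum (centres at TS means)."""
    best = math.inf
    for part in set_partitions(list(scene.ids)):
        best = min(best, oracle_partition_energy(scene, part, params))
    return best


def oracle_best_subset_energy(
    scene: Scene, candidates: list[tuple[float, float]], params: ModelParams
) -> float:
    """Exhaustive minimum over non-empty candidate subsets, persons to
    their cheapest selected candidate."""
    costs = []
    for p in scene:
        tu, tv = oracle_ts(p, params.stride_D)
        row = []
        for cu, cv in candidates:
            c = (cu - tu) ** 2 + (cv - tv) ** 2
            if params.use_visibility:
                c += oracle_vis_penalty(scene, p, (cu, cv), params)
            row.append(c)
        costs.append(row)
    m = len(candidates)
    best = math.inf
    for mask in range(1, 2**m):
        idx = [k for k in range(m) if (mask >> k) & 1]
        total = params.label_cost * len(idx)
        for row in costs:
            total += min(row[k] for k in idx)
        best = min(best, total)
    return best
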