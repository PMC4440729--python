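"""Unit tests for the domain types and energy terms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcff import (
    Assignment,
    GroupSet,
    ModelParams,
    OSpaceCentre,
    PersonState,
    Scene,
    person_visibility_penalty,
    scene_cost,
    ts_centre,
    unary_cost,
    visibility_cost,
)
from gcff.core import (
    DegenerateGeometryError,
    InconsistentAssignmentError,
    InvalidInputError,
    transform_scene,
)

from conftest import make_random_scene


class TestPersonState:
    def test_theta_normalised_to_half_open_interval(self):
        assert PersonState(0, 0, 0, 3 * math.pi).theta == pytest.approx(math.pi)
        assert PersonState(0, 0, 0, -math.pi).theta == pytest.approx(math.pi)
        assert PersonState(0, 0, 0, 2 * math.pi).theta == pytest.approx(0.0)

    @given(st.floats(-100.0, 100.0))
    @settings(deadline=None, derandomize=True)
    def test_theta_wrap_preserves_direction(self, theta):
        p = PersonState(0, 0, 0, theta)
        assert -math.pi < p.theta <= math.pi
        assert math.cos(p.theta) == pytest.approx(math.cos(theta), abs=1e-9)
        assert math.sin(p.theta) == pytest.approx(math.sin(theta), abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            PersonState(0, math.nan, 0, 0)
        with pytest.raises(InvalidInputError):
            PersonState(0, 0, 0, math.inf)

    def test_scene_rejects_duplicate_ids(self):
        with pytest.raises(InvalidInputError):
            Scene(persons=(PersonState(0, 0, 0, 0), PersonState(0, 1, 1, 0)))


class TestGroupSet:
    def test_rejects_undersized_groups(self):
        with pytest.raises(InvalidInputError):
            GroupSet(groups=(frozenset({1}),))

    def test_rejects_overlapping_membership(self):
        with pytest.raises(InvalidInputError):
            GroupSet(groups=(frozenset({1, 2}), frozenset({2, 3})))
        with pytest.raises(InvalidInputError):
            GroupSet(groups=(frozenset({1, 2}),), singletons=frozenset({2}))

    def test_equality_ignores_group_order(self):
        a = GroupSet(groups=(frozenset({1, 2}), frozenset({3, 4})))
        b = GroupSet(groups=(frozenset({3, 4}), frozenset({1, 2})))
        assert a == b


class TestTsCentre:
    @pytest.mark.parametrize(
        "x, y, theta, D, expected",
        [
            (0, 0, 0, 30, (30, 0)),
            (0, 0, math.pi / 2, 30, (0, 30)),
            (10, -5, math.pi, 20, (-10, -5)),
        ],
    )
    def test_one_stride_ahead(self, x, y, theta, D, expected):
        c = ts_centre(PersonState(0, x, y, theta), D)
        assert (c.u, c.v) == pytest.approx(expected, abs=1e-12)

    def test_requires_positive_stride(self):
        with pytest.raises(InvalidInputError):
            ts_centre(PersonState(0, 0, 0, 0), 0.0)


class TestUnaryCost:
    def test_zero_at_own_ts_centre(self, params):
        p = PersonState(0, 3.0, 7.0, 1.1)
        mu = ts_centre(p, params.stride_D)
        assert unary_cost(p, OSpaceCentre(mu.u, mu.v), params) == pytest.approx(0.0)

    def test_squared_euclidean_distance(self, params):
        p = PersonState(0, 0, 0, 0)  # mu = (30, 0)
        assert unary_cost(p, OSpaceCentre(30, 10), params) == pytest.approx(100.0)
        p2 = PersonState(0, -30, 0, 0)  # mu = (0, 0)
        assert unary_cost(p2, OSpaceCentre(3, 4), params) == pytest.approx(25.0)


class TestVisibilityCost:
    def test_zero_when_person_is_closer(self, params):
        i = PersonState(0, 0, 1, 0)
        j = PersonState(1, 0, 2, 0)
        assert visibility_cost(i, j, OSpaceCentre(0, 0), params) == 0.0

    def test_zero_on_distance_tie(self, params):
        i = PersonState(0, 0, 1, 0)
        j = PersonState(1, 1, 0, 0)
        assert visibility_cost(i, j, OSpaceCentre(0, 0), params) == 0.0

    def test_collinear_occlusion_penalty(self, params):
        # j directly between i and the centre: theta_ij = 0,
        # penalty = exp(K * 1) * (2 - 1) / 1 = e
        i = PersonState(0, 0, 2, 0)
        j = PersonState(1, 0, 1, 0)
        got = visibility_cost(i, j, OSpaceCentre(0, 0), params)
        assert got == pytest.approx(math.e, rel=1e-12)

    def test_zero_outside_occlusion_window(self, params):
        # quarter-turn separation is far beyond theta_hat = pi/6
        i = PersonState(0, 2, 0, 0)
        j = PersonState(1, 0, 1, 0)
        assert visibility_cost(i, j, OSpaceCentre(0, 0), params) == 0.0

    def test_degenerate_centre_on_occluder(self, params):
        i = PersonState(0, 0, 2, 0)
        j = PersonState(1, 0, 0, 0)
        with pytest.raises(DegenerateGeometryError):
            visibility_cost(i, j, OSpaceCentre(0, 0), params)

    def test_non_negative_on_random_geometry(self, params):
        rng = np.random.default_rng(7)
        for _ in range(200):
            i = PersonState(0, *rng.uniform(-5, 5, 2), rng.uniform(-3, 3))
            j = PersonState(1, *rng.uniform(-5, 5, 2), rng.uniform(-3, 3))
            assert visibility_cost(i, j, OSpaceCentre(0.1, 0.2), params) >= 0.0


class TestPersonVisibilityPenalty:
    def test_empty_sum_for_lone_person(self, params):
        i = PersonState(0, 0, 5, 0)
        scene = Scene(persons=(i,))
        assert person_visibility_penalty(i, scene, OSpaceCentre(0, 0), params) == 0.0

    def test_zero_when_closest_to_centre(self, params):
        persons = (
            PersonState(0, 0, 1, 0),
            PersonState(1, 0, 3, 0),
            PersonState(2, 2, 2, 0),
        )
        scene = Scene(persons=persons)
        assert (
            person_visibility_penalty(persons[0], scene, OSpaceCentre(0, 0), params)
            == 0.0
        )

    def test_collinear_three_person_sum(self, params):
        # i farthest on a line through the centre: both others occlude.
        # penalties: exp(K)*(3-1)/1 = 2e and exp(K)*(3-2)/2 = e/2
        persons = (
            PersonState(0, 0, 3, 0),
            PersonState(1, 0, 1, 0),
            PersonState(2, 0, 2, 0),
        )
        scene = Scene(persons=persons)
        got = person_visibility_penalty(persons[0], scene, OSpaceCentre(0, 0), params)
        assert got == pytest.approx(2 * math.e + math.e / 2, rel=1e-12)


class TestSceneCost:
    def test_single_person_pays_one_label_cost(self, params):
        p = PersonState(0, 0, 0, 0)
        mu = ts_centre(p, params.stride_D)
        a = Assignment(
            labels={0: 0}, centres={0: OSpaceCentre(mu.u, mu.v, label=0)}
        )
        assert scene_cost(Scene(persons=(p,)), a, params) == pytest.approx(
            params.sigma**2
        )

    def test_facing_pair_shared_centre_zero_residual(self, params):
        D = params.stride_D
        pair = (PersonState(0, -D, 0, 0), PersonState(1, D, 0, math.pi))
        a = Assignment(labels={0: 0, 1: 0}, centres={0: OSpaceCentre(0, 0, label=0)})
        assert scene_cost(Scene(persons=pair), a, params) == pytest.approx(
            params.sigma**2
        )

    def test_pair_residuals_add_two_r_squared(self, params):
        r = 25.0
        D = params.stride_D
        # TS centres at (+-r, 0); shared centre at the midpoint
        pair = (
            PersonState(0, -r - D, 0, 0),
            PersonState(1, r + D, 0, math.pi),
        )
        a = Assignment(labels={0: 0, 1: 0}, centres={0: OSpaceCentre(0, 0, label=0)})
        assert scene_cost(Scene(persons=pair), a, params) == pytest.approx(
            params.sigma**2 + 2 * r**2
        )

    def test_missing_centre_raises(self, params):
        p = PersonState(0, 0, 0, 0)
        a = Assignment(labels={0: 5}, centres={})
        with pytest.raises(InconsistentAssignmentError):
            scene_cost(Scene(persons=(p,)), a, params)

    def test_mdl_lower_bound_without_visibility(self, params_novis):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scene = make_random_scene(rng, int(rng.integers(2, 6)))
            mu = scene.ts_centres(params_novis.stride_D)
            centre = mu.mean(axis=0)
            a = Assignment(
                labels={p.id: 0 for p in scene},
                centres={0: OSpaceCentre(*centre, label=0)},
            )
            cost = scene_cost(scene, a, params_novis)
            assert cost >= params_novis.label_cost - 1e-9


class TestGeometricInvariances:
    def test_rigid_motion_leaves_cost_unchanged(self, params):
        rng = np.random.default_rng(11)
        for _ in range(10):
            scene = make_random_scene(rng, 5)
            a = Assignment(
                labels={p.id: p.id for p in scene},
                centres={
                    p.id: OSpaceCentre(p.x + 10.0, p.y - 4.0, label=p.id)
                    for p in scene
                },
            )
            base = scene_cost(scene, a, params)
            rot = float(rng.uniform(0, 2 * math.pi))
            t = rng.uniform(-50, 50, 2)
            moved = transform_scene(scene, rotation=rot, translation=t)
            c, s = math.cos(rot), math.sin(rot)
            moved_a = Assignment(
                labels=dict(a.labels),
                centres={
                    lab: OSpaceCentre(
                        c * ctr.u - s * ctr.v + t[0],
                        s * ctr.u + c * ctr.v + t[1],
                        label=lab,
                    )
                    for lab, ctr in a.centres.items()
                },
            )
            assert scene_cost(moved, moved_a, params) == pytest.approx(base, rel=1e-9)

    def test_scale_covariance_of_least_squares_term(self, params_novis):
        rng = np.random.default_rng(12)
        scene = make_random_scene(rng, 6)
        a = Assignment(
            labels={p.id: 0 for p in scene},
            centres={0: OSpaceCentre(150.0, 150.0, label=0)},
        )
        base = scene_cost(scene, a, params_novis)
        s = 2.5
        scaled_scene = transform_scene(scene, scale=s)
        scaled_params = ModelParams(
            stride_D=s * params_novis.stride_D,
            sigma=s * params_novis.sigma,
            use_visibility=False,
        )
        scaled_a = Assignment(
            labels=dict(a.labels),
            centres={0: OSpaceCentre(150.0 * s, 150.0 * s, label=0)},
        )
        assert scene_cost(scaled_scene, scaled_a, scaled_params) == pytest.approx(
            s**2 * base, rel=1e-9
        )

    def test_visibility_term_is_scale_invariant(self, params):
        i = PersonState(0, 0, 2, 0)
        j = PersonState(1, 0, 1, 0)
        base = visibility_cost(i, j, OSpaceCentre(0, 0), params)
        s = 7.0
        scaled = visibility_cost(
            PersonState(0, 0, 2 * s, 0),
            PersonState(1, 0, 1 * s, 0),
            OSpaceCentre(0, 0),
            params,
        )
        assert scaled == pytest.approx(base, rel=1e-12)
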