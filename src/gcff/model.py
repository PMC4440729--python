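"""Model/Results interface for conversational-group detection.

:class:`GCFFModel` wraps a single frame (a :class:`~gcff.core.Scene`)
together with the energy parameters; :meth:`GCFFModel.fit` runs the
alternating minimisation and returns a :class:`GCFFResults` carrying
the detected groups, the final o-space centres, the energy trace and
evaluation helpers.

Example
-------
>>> import pandas as pd
>>> from gcff import GCFFModel
>>> df = pd.DataFrame({
...     "id": [0, 1, 2],
...     "x": [0.0, 60.0, 300.0],
...     "y": [0.0, 0.0, 0.0],
...     "theta": [0.0, 3.14159265, 3.14159265 / 2],
... })
>>> res = GCFFModel.from_dataframe(df, stride_D=30, sigma=80).fit()
>>> res.groups.as_lists()
[[0, 1]]
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np
import pandas as pd

from .core import Assignment, GroupSet, ModelParams, PersonState, Scene
from .metrics import GTM_GRID, precision_recall_f1, tolerant_match
from .optimize import SolverTrace, gcff_detect

__all__ = ["GCFFModel", "GCFFResults"]


class GCFFModel:
    """Conversational-group detection model for one frame.

    Parameters
    ----------
    scene : Scene
        The frame to analyse (positions and head orientations).
    params : ModelParams, optional
        Energy parameters; keyword overrides are applied on top, e.g.
        ``GCFFModel(scene, sigma=45)``.
    """

    def __init__(self, scene: Scene, params: ModelParams | None = None, **overrides: Any):
        self.scene = scene
        base = params or ModelParams()
        self.params = replace(base, **overrides) if overrides else base

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        truth: GroupSet | None = None,
        unit: str = "cm",
        degrees: bool = False,
        params: ModelParams | None = None,
        **overrides: Any,
    ) -> "GCFFModel":
        """Build a model from a DataFrame with id/x/y/theta columns."""
        missing = {"id", "x", "y", "theta"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        theta = np.deg2rad(df["theta"]) if degrees else df["theta"]
        persons = tuple(
            PersonState(i, float(x), float(y), float(t))
            for i, x, y, t in zip(df["id"], df["x"], df["y"], theta)
        )
        scene = Scene(persons=persons, truth=truth, unit=unit)
        return cls(scene, params=params, **overrides)

    def fit(self) -> "GCFFResults":
        """Run the alternating minimisation to convergence."""
        groups, assignment, trace = gcff_detect(self.scene, self.params)
        return GCFFResults(self, groups, assignment, trace)


class GCFFResults:
    """Fitted detection: groups, centres, energy trace, diagnostics."""

    def __init__(
        self,
        model: GCFFModel,
        groups: GroupSet,
        assignment: Assignment,
        trace: SolverTrace,
    ):
        self.model = model
        self.groups = groups
        self.assignment = assignment
        self.trace = trace

    # -- diagnostics -----------------------------------------------------
    @property
    def energy(self) -> float:
        """Final value of the minimised objective (squared length units)."""
        return self.assignment.energy

    @property
    def converged(self) -> bool:
        return self.trace.converged

    @property
    def n_groups(self) -> int:
        return len(self.groups.groups)

    @property
    def n_singletons(self) -> int:
        return len(self.groups.singletons)

    def centres_frame(self) -> pd.DataFrame:
        """O-space centres with member counts as a DataFrame."""
        counts: dict = {}
        for pid, lab in self.assignment.labels.items():
            counts[lab] = counts.get(lab, 0) + 1
        rows = [
            {
                "label": lab,
                "u": c.u,
                "v": c.v,
                "members": counts.get(lab, 0),
            }
            for lab, c in sorted(self.assignment.centres.items(), key=lambda kv: repr(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["label", "u", "v", "members"])

    def score(self, truth: GroupSet | None = None, T: float = 1.0):
        """Precision/recall/F1 against ground truth at tolerance T."""
        truth = truth if truth is not None else self.model.scene.truth
        if truth is None:
            raise ValueError("no ground truth available to score against")
        return precision_recall_f1(tolerant_match(self.groups, truth, T))

    def summary(self) -> str:
        """Human-readable report of the fit."""
        p = self.model.params
        lines = [
            "Conversational group detection (graph-cuts F-formation fit)",
            "=" * 60,
            f"persons: {len(self.model.scene):>4}    unit: {self.model.scene.unit}",
            f"stride D: {p.stride_D:g}    sigma: {p.sigma:g}    "
            f"MDL weight: {p.label_cost:g}",
            f"visibility: {'on' if p.use_visibility else 'off'} "
            f"(theta_hat={p.vis_theta_hat:.4g} rad, K={p.vis_K:g})",
            "-" * 60,
            f"energy: {self.energy:.6g}    iterations: {self.trace.iterations}"
            f"    converged: {self.converged}",
            f"groups: {self.n_groups}    singletons: {self.n_singletons}",
        ]
        for idx, members in enumerate(self.groups.as_lists()):
            lines.append(f"  group {idx}: {members}")
        if self.groups.singletons:
            lines.append(
                f"  singletons: {sorted(self.groups.singletons, key=repr)}"
            )
        if self.model.scene.truth is not None:
            prec, rec, f1 = self.score(T=1.0)
            lines.append("-" * 60)
            lines.append(
                f"vs ground truth (T=1): precision={prec:.3f} "
                f"recall={rec:.3f} F1={f1:.3f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Debug plot: people, facing arrows, detected o-space centres."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        scene = self.model.scene
        D = self.model.params.stride_D
        palette = plt.rcParams["axes.prop_cycle"].by_key()["color"]
        lab_colour = {
            lab: palette[i % len(palette)]
            for i, lab in enumerate(sorted(self.assignment.centres, key=repr))
        }
        for p in scene:
            colour = lab_colour.get(self.assignment.labels.get(p.id), "grey")
            ax.plot(p.x, p.y, "o", color=colour)
            ax.annotate(
                "",
                xy=(p.x + D * np.cos(p.theta), p.y + D * np.sin(p.theta)),
                xytext=(p.x, p.y),
                arrowprops=dict(arrowstyle="->", color=colour, lw=1),
            )
            ax.annotate(str(p.id), (p.x, p.y), textcoords="offset points", xytext=(4, 4))
        for lab, c in self.assignment.centres.items():
            ax.plot(c.u, c.v, "x", color=lab_colour[lab], markersize=10, mew=2)
        ax.set_aspect("equal")
        ax.set_xlabel(f"x [{scene.unit}]")
        ax.set_ylabel(f"y [{scene.unit}]")
        return ax
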