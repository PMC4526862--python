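"""Shared fixtures: geometric helpers and phantom reconstructions.

The heavyweight full-stack reconstructions are session-scoped so the
accuracy, density-robustness and interference tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import rayshell as rs

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def circle_boundary(cx: float, cy: float, radius: float, n: int = 64) -> rs.ClosedBoundary:
    theta = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    return rs.ClosedBoundary(pts)


def square_boundary(x0: float, y0: float, side: float) -> rs.ClosedBoundary:
    """Axis-aligned CCW square as 8 points (corners + edge midpoints)."""
    h = side / 2.0
    pts = np.array(
        [
            [x0, y0],
            [x0 + h, y0],
            [x0 + side, y0],
            [x0 + side, y0 + h],
            [x0 + side, y0 + side],
            [x0 + h, y0 + side],
            [x0, y0 + side],
            [x0, y0 + h],
        ]
    )
    return rs.ClosedBoundary(pts)


def stack_scores(model: rs.SurfaceModel, truths, height: int, width: int):
    recalls, precisions = [], []
    for b, t in zip(model.boundaries, truths):
        s = rs.recall_precision(t, b, height, width)
        recalls.append(s.recall)
        precisions.append(s.precision)
    return np.asarray(recalls), np.asarray(precisions)


@pytest.fixture(scope="session")
def standard_phantom_data():
    spec = rs.standard_phantom(seed=0)
    stack, truths = rs.generate_phantom(spec)
    return spec, stack, truths


@pytest.fixture(scope="session")
def standard_reconstruction(standard_phantom_data):
    """Full-pipeline run on the standard phantom with default parameters."""
    spec, stack, truths = standard_phantom_data
    model = rs.reconstruct_stack(stack, truths[0], rs.SolverParams())
    return spec, truths, model


@pytest.fixture(scope="session")
def blob_free_reconstruction():
    spec = rs.standard_phantom(seed=0, blob=False)
    stack, truths = rs.generate_phantom(spec)
    model = rs.reconstruct_stack(stack, truths[0], rs.SolverParams())
    return spec, truths, model
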