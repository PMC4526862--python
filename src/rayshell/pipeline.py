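"""Slice-wise surface reconstruction.

One slice is refined by composing the ray-resampling chain with the offset
solver; a stack is reconstructed by threading each slice's result in as the
initial boundary of the next slice.  This propagation relies on the target
surface varying slowly along z, so consecutive true boundaries differ by at
most a few pixels -- well inside the solver's annealed capture range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, RayshellError
from .resampling import (
    ClosedBoundary,
    ImageSlice,
    build_ray_field,
    resample_closed_polyline,
)
from .solver import SolverParams, boundary_from_offsets, evolve_offsets

__all__ = ["SliceStatus", "SurfaceModel", "reconstruct_slice", "reconstruct_stack"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SliceStatus:
    """Per-slice convergence record."""

    z: int
    converged: bool
    failed: bool
    iterations: int
    residual: float


@dataclass
class SurfaceModel:
    """Z-ordered reconstructed boundaries forming a closed surface.

    ``voxel_size`` is the physical (x, y, z) size of one voxel, used when
    exporting meshes in physical units.
    """

    boundaries: list[ClosedBoundary]
    z_range: tuple[int, int]
    per_slice_status: list[SliceStatus]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        if len(self.boundaries) != len(self.per_slice_status):
            raise ParameterError("one status per boundary required")
        counts = {len(b) for b in self.boundaries}
        if len(counts) > 1:
            raise ParameterError("all boundaries must share the discretization N")

    @property
    def n_slices(self) -> int:
        return len(self.boundaries)


def reconstruct_slice(
    slice_: ImageSlice,
    init_boundary: ClosedBoundary,
    params: SolverParams,
    return_solution: bool = False,
):
    """Refine one slice's boundary from an initial closed boundary.

    Pipeline: equal-arc resampling to N points -> exterior normals -> ray
    sampling and conditioning -> offset evolution -> displaced boundary,
    re-resampled to N points.
    """
    boundary = resample_closed_polyline(init_boundary, params.n_points)
    rays = build_ray_field(slice_, boundary, params.M, params.smoothing_passes)
    solution = evolve_offsets(rays, params)
    refined = boundary_from_offsets(boundary, rays.normals, solution)
    refined = resample_closed_polyline(refined, params.n_points)
    if return_solution:
        return refined, solution
    return refined


def _slice_order(n: int, start_z: int, direction: str) -> list[list[int]]:
    if direction == "forward":
        return [list(range(start_z, n))]
    if direction == "backward":
        return [list(range(start_z, -1, -1))]
    if direction == "both":
        return [list(range(start_z, n)), list(range(start_z - 1, -1, -1))]
    raise ParameterError(f"unknown direction {direction!r}")


def reconstruct_stack(
    stack: list[ImageSlice],
    init_boundary: ClosedBoundary,
    params: SolverParams,
    start_z: int = 0,
    direction: str = "forward",
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> SurfaceModel:
    """Reconstruct a surface by propagating boundaries slice to slice.

    Each reconstructed boundary seeds the next slice.  ``direction='both'``
    runs forward and backward from ``start_z`` with the same seed.  A slice
    that fails (e.g. irreparable self-intersection) reuses the previous
    boundary and is flagged, so one bad slice cannot terminate a run.
    """
    if len(stack) == 0:
        raise ParameterError("empty stack")
    if not (0 <= start_z < len(stack)):
        raise ParameterError("start_z outside the stack")

    results: dict[int, tuple[ClosedBoundary, SliceStatus]] = {}
    for run in _slice_order(len(stack), start_z, direction):
        if not run:
            continue
        current = init_boundary
        for z in run:
            if direction == "both" and z in results:
                continue
            try:
                refined, sol = reconstruct_slice(
                    stack[z], current, params, return_solution=True
                )
                status = SliceStatus(
                    z=z,
                    converged=sol.converged,
                    failed=False,
                    iterations=sol.iterations,
                    residual=sol.residual_history[-1],
                )
                current = refined
            except RayshellError as exc:
                logger.warning("slice %d failed: %s; reusing previous boundary", z, exc)
                refined = resample_closed_polyline(current, params.n_points)
                status = SliceStatus(
                    z=z, converged=False, failed=True, iterations=0, residual=float("nan")
                )
                current = refined
            results[z] = (refined, status)
            logger.info(
                "slice %d: iterations=%d residual=%.3g converged=%s",
                z,
                status.iterations,
                status.residual,
                status.converged,
            )

    zs = sorted(results)
    return SurfaceModel(
        boundaries=[results[z][0] for z in zs],
        z_range=(zs[0], zs[-1]),
        per_slice_status=[results[z][1] for z in zs],
        voxel_size=voxel_size,
    )
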