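"""Convergence (negative divergence) maps of displacement fields.

Optical flow alone cannot tell active contraction from passive translation
of a cell layer.  The divergence removes any uniform translation, so the
convergence map (minus the divergence) highlights where tissue is pulled
inward — the contractile centers — and its magnitude is a numerical
estimate of contractile strength.  Units are displacement per grid spacing
relative to the reference state (per frame interval, not per second).

Sign convention: inward flow (contraction) gives positive convergence; an
expanding field of the same shape gives negative values of equal
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .errors import InputError
from .flow import DisplacementField, TileGrid, tps_smooth

__all__ = [
    "ConvergenceMap",
    "ContractileCenterCall",
    "divergence",
    "convergence_series",
    "locate_centers",
    "default_threshold",
]

_PLUS_STENCIL = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ConvergenceMap:
    """Scalar convergence per grid center for one frame."""

    grid: TileGrid
    values: np.ndarray  # (grid_rows, grid_cols)
    flagged: np.ndarray  # (grid_rows, grid_cols) bool: one-sided stencil or
    # stencil touching an invalid vector
    t: int | None = None

    def interior_max(self) -> float:
        ok = ~self.flagged
        if not ok.any():
            return float("nan")
        return float(self.values[ok].max())


@dataclass
class ContractileCenterCall:
    position: tuple[float, float]  # pixels (row, col)
    peak_convergence: float
    frame_of_peak: int


def divergence(fld: DisplacementField) -> ConvergenceMap:
    """Convergence map of one field: minus its central-difference divergence.

    ``div = d(drow)/drow + d(dcol)/dcol`` with second-order central
    differences on the tile grid (spacing = grid step); border centers use
    one-sided differences and are flagged, as are centers whose stencil
    touches an invalid vector.  Adding a constant vector everywhere leaves
    interior values unchanged to machine precision, and the map is linear
    in the field.
    """
    grid = fld.grid
    if not grid.is_uniform():
        raise InputError("convergence needs a regular lattice of tile centers")
    gr, gc = grid.shape
    if gr < 2 or gc < 2:
        raise InputError("grid too small for divergence stencils")
    v = fld.vectors_2d()
    h = float(grid.step)
    ddr = np.gradient(v[..., 0], h, axis=0)
    ddc = np.gradient(v[..., 1], h, axis=1)
    conv = -(ddr + ddc)
    flagged = np.zeros((gr, gc), dtype=bool)
    flagged[0, :] = flagged[-1, :] = True
    flagged[:, 0] = flagged[:, -1] = True
    invalid = ~fld.valid_2d()
    if invalid.any():
        flagged |= binary_dilation(invalid, structure=_PLUS_STENCIL)
    return ConvergenceMap(grid=grid, values=conv, flagged=flagged, t=fld.t)


def convergence_series(
    fields: list[DisplacementField],
    presmooth: float | str | None = "gcv",
) -> tuple[list[ConvergenceMap], np.ndarray]:
    """Per-frame convergence maps plus a contraction-strength trace.

    With ``presmooth`` set (the default), each field is first smoothed by a
    thin-plate spline evaluated back on the grid, suppressing the
    integer-pixel matching noise that differentiation would amplify; pass
    ``presmooth=None`` to differentiate the raw field.  The strength trace
    is the per-frame maximum convergence over unflagged centers.
    """
    if not fields:
        raise InputError("no fields given")
    grid = fields[0].grid
    for f in fields:
        if f.grid.shape != grid.shape or f.grid.step != grid.step:
            raise InputError("fields must share one grid")
    maps = []
    for f in fields:
        g = tps_smooth(f, presmooth) if presmooth is not None else f
        m = divergence(g)
        m.t = f.t
        maps.append(m)
    strength = np.array([m.interior_max() for m in maps])
    return maps, strength


def default_threshold(
    maps: list[ConvergenceMap],
    factor: float = 3.0,
    rel_floor: float = 0.1,
    rest_fraction: float = 0.25,
) -> float:
    """Detection threshold: ``factor`` x median absolute rest convergence.

    Rest frames are taken as the ``rest_fraction`` of frames with the
    lowest mean absolute convergence; their median absolute value
    approximates the noise floor of the resting state.  A relative floor
    of ``rel_floor`` times the global peak guards the noiseless limit,
    where the rest median is (near) zero and arbitrarily weak ripples
    would otherwise be called.
    """
    per_frame = [np.abs(m.values[~m.flagged]).ravel() for m in maps]
    per_frame = [v for v in per_frame if v.size]
    if not per_frame:
        raise InputError("no unflagged convergence values")
    activity = np.array([v.mean() for v in per_frame])
    n_rest = max(1, int(np.ceil(rest_fraction * len(per_frame))))
    rest_idx = np.argsort(activity, kind="stable")[:n_rest]
    rest = np.concatenate([per_frame[i] for i in rest_idx])
    peak = max(float(v.max()) for v in per_frame)
    return max(factor * float(np.median(rest)), rel_floor * peak)


def locate_centers(
    maps: list[ConvergenceMap],
    threshold: float | None = None,
    min_separation: float = 32.0,
) -> list[ContractileCenterCall]:
    """Call contractile centers from the time-maximum convergence map.

    Local maxima (8-neighbourhood) of the per-center maximum over time
    exceeding ``threshold`` are pruned greedily so surviving calls are at
    least ``min_separation`` pixels apart, and returned sorted by peak
    convergence, descending.  May return an empty list.
    """
    if not maps:
        raise InputError("no maps given")
    if threshold is None:
        threshold = default_threshold(maps)
    grid = maps[0].grid
    stack = np.stack([m.values for m in maps])  # (T, gr, gc)
    flagged = np.stack([m.flagged for m in maps])
    masked = np.where(flagged, -np.inf, stack)
    tmax = masked.max(axis=0)
    argt = masked.argmax(axis=0)

    gr, gc = tmax.shape
    padded = np.pad(tmax, 1, constant_values=-np.inf)
    is_peak = np.ones((gr, gc), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            is_peak &= tmax >= padded[1 + dr : 1 + dr + gr, 1 + dc : 1 + dc + gc]
    is_peak &= np.isfinite(tmax) & (tmax > threshold)

    rr, cc = np.nonzero(is_peak)
    if rr.size == 0:
        return []
    vals = tmax[rr, cc]
    order = np.argsort(-vals, kind="stable")
    rows = grid.row_centers[rr[order]].astype(float)
    cols = grid.col_centers[cc[order]].astype(float)
    kept: list[ContractileCenterCall] = []
    for i in range(rr.size):
        p = np.array([rows[i], cols[i]])
        if any(
            np.hypot(p[0] - k.position[0], p[1] - k.position[1]) < min_separation
            for k in kept
        ):
            continue
        kept.append(
            ContractileCenterCall(
                position=(float(p[0]), float(p[1])),
                peak_convergence=float(vals[order[i]]),
                frame_of_peak=int(argt[rr[order[i]], cc[order[i]]]),
            )
        )
    return kept
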