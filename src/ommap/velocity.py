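"""Conduction velocity from the local-activation-time surface.

For each pixel the activation time T(x, y) is fitted by a low-order
polynomial over a circular pixel neighborhood (least squares), the spatial
gradient g = grad T is taken at the center, and the velocity is the
inverse-gradient vector

    v = g / |g|^2

which points along propagation with speed 1/|g|.  With T in ms and
distances in mm, 1 ms/mm == 1 s/m, so speed in m/s is simply 1/|g|.
Pixels with a vanishing gradient (quasi-simultaneous activation) or with
implausibly high speed are marked invalid rather than classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import LatMap

__all__ = ["CvMap", "cv_map", "REASONS"]

#: Invalidity reason codes stored per pixel.
REASONS = {
    0: "valid",
    1: "undefined LAT",
    2: "underdetermined fit",
    3: "flat gradient",
    4: "implausible speed",
}


@dataclass
class CvMap:
    """Per-pixel conduction velocity vectors and speed in m/s.

    ``vx`` points along +columns, ``vy`` along +rows; all three planes are
    NaN where ``valid`` is False, and ``reason`` explains why (codes in
    :data:`REASONS`).
    """

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def exclusion_counts(self) -> dict[str, int]:
        return {
            name: int((self.reason == code).sum())
            for code, name in REASONS.items()
            if code != 0
        }


def _neighborhood_offsets(radius_px: int) -> np.ndarray:
    """(dr, dc) offsets within a Euclidean radius, center included."""
    r = int(radius_px)
    d = np.arange(-r, r + 1)
    dr, dc = np.meshgrid(d, d, indexing="ij")
    keep = dr**2 + dc**2 <= radius_px**2
    return np.stack([dr[keep], dc[keep]], axis=1)


def _design(offsets_mm: np.ndarray, poly_order: int) -> np.ndarray:
    """Polynomial design matrix; columns 1 and 2 are the x and y slopes."""
    x = offsets_mm[:, 1]
    y = offsets_mm[:, 0]
    cols = [np.ones_like(x), x, y]
    if poly_order == 2:
        cols += [x * x, x * y, y * y]
    return np.stack(cols, axis=1)


def cv_map(
    lat: LatMap,
    fit_radius_px: int = 3,
    poly_order: int = 2,
    speed_cap_mps: float = 2.0,
    gradient_floor_s_per_m: float = 1e-6,
) -> CvMap:
    """Estimate the conduction-velocity field from a LAT map.

    Parameters
    ----------
    lat
        Activation-time map (ms); NaN pixels are skipped.
    fit_radius_px
        Radius of the circular fit neighborhood, in pixels.
    poly_order
        1 (planar fit) or 2 (quadratic surface, the default).
    speed_cap_mps
        Speeds above this physiological cap are marked invalid
        ("implausible speed") instead of entering region statistics.
    gradient_floor_s_per_m
        |grad T| below this marks the pixel "flat gradient".
    """
    if poly_order not in (1, 2):
        raise ValueError("poly_order must be 1 or 2")
    if fit_radius_px < 1:
        raise ValueError("fit_radius_px must be >= 1")
    t = lat.lat_ms
    rows, cols = t.shape
    px = lat.pixel_size_mm
    offsets = _neighborhood_offsets(fit_radius_px)
    design = _design(offsets * px, poly_order)
    ncoef = design.shape[1]
    pinv = np.linalg.pinv(design)  # (ncoef, n_off)

    # stack of neighbor LATs: (n_off, rows, cols), NaN outside the grid
    pad = fit_radius_px
    padded = np.pad(t, pad, constant_values=np.nan)
    stack = np.empty((len(offsets), rows, cols))
    for i, (dr, dc) in enumerate(offsets):
        stack[i] = padded[pad + dr : pad + dr + rows, pad + dc : pad + dc + cols]

    defined = np.isfinite(t)
    finite = np.isfinite(stack)
    n_finite = finite.sum(axis=0)
    full = finite.all(axis=0)

    gx = np.full((rows, cols), np.nan)
    gy = np.full((rows, cols), np.nan)
    reason = np.full((rows, cols), 1, dtype=np.uint8)
    reason[defined] = 2  # until a fit succeeds

    # fast path: complete neighborhoods share one pseudo-inverse
    if full.any():
        coef = np.einsum("kn,nij->kij", pinv, np.where(finite, stack, 0.0))
        sel = full & defined
        gx[sel] = coef[1][sel]
        gy[sel] = coef[2][sel]
        reason[sel] = 0

    # slow path: incomplete but still overdetermined neighborhoods
    partial = defined & ~full & (n_finite >= ncoef)
    for r, c in np.argwhere(partial):
        good = finite[:, r, c]
        a = design[good]
        if np.linalg.matrix_rank(a) < ncoef:
            continue
        coefs, *_ = np.linalg.lstsq(a, stack[good, r, c], rcond=None)
        gx[r, c], gy[r, c] = coefs[1], coefs[2]
        reason[r, c] = 0

    gmag = np.hypot(gx, gy)  # ms/mm == s/m
    fitted = reason == 0
    flat = fitted & (gmag < gradient_floor_s_per_m)
    reason[flat] = 3
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = 1.0 / gmag
        vx = gx / gmag**2
        vy = gy / gmag**2
    implausible = fitted & ~flat & (speed > speed_cap_mps)
    reason[implausible] = 4

    valid = reason == 0
    if not valid.any():
        raise ValueError("conduction-velocity map has no valid pixel")
    for arr in (vx, vy, speed):
        arr[~valid] = np.nan
    out = CvMap(
        vx=vx,
        vy=vy,
        speed=speed,
        valid=valid,
        reason=reason,
        provenance={
            "fit_radius_px": fit_radius_px,
            "poly_order": poly_order,
            "speed_cap_mps": speed_cap_mps,
            "gradient_floor_s_per_m": gradient_floor_s_per_m,
        },
    )
    out.provenance["excluded"] = out.exclusion_counts()
    return out
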