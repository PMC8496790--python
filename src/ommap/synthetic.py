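"""Synthetic movie and study-table generation with known ground truth.

Movies are built from a prescribed conduction-speed field: activation times
come from a fast-marching (eikonal) front propagation over the pixel grid,
every pixel then receives an action-potential-shaped trace (sigmoid
upstroke, plateau, exponential recovery) starting at its activation time,
and baseline drift plus Gaussian noise are added last.  The generator also
produces clustered outcome tables (animal x pacing position x S1/S2 train)
with prescribed fixed effects and a between-animal random effect, for
exercising the study-level statistics.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import VoltageMovie

__all__ = [
    "Patch",
    "SceneSpec",
    "GroundTruth",
    "EffectSpec",
    "StudyDesign",
    "eikonal_travel_time",
    "make_movie",
    "make_study_table",
    "save_ground_truth",
]

#: Slow-conduction threshold used for ground-truth masks, m/s.
SC_THRESHOLD_MPS = 0.2

EDGE_SOURCES = ("top", "bottom", "left", "right")


@dataclass(frozen=True)
class Patch:
    """A region of overridden conduction speed.

    ``kind`` is ``"rect"`` (fields r0, r1, c0, c1; half-open pixel ranges)
    or ``"disk"`` (fields r, c, radius_px).
    """

    kind: str
    speed_mps: float
    r0: int = 0
    r1: int = 0
    c0: int = 0
    c1: int = 0
    r: float = 0.0
    c: float = 0.0
    radius_px: float = 0.0

    def footprint(self, rows: int, cols: int) -> np.ndarray:
        rr, cc = np.mgrid[0:rows, 0:cols]
        if self.kind == "rect":
            return (rr >= self.r0) & (rr < self.r1) & (cc >= self.c0) & (cc < self.c1)
        if self.kind == "disk":
            return (rr - self.r) ** 2 + (cc - self.c) ** 2 <= self.radius_px**2
        raise ValueError(f"unknown patch kind {self.kind!r}")


@dataclass
class SceneSpec:
    """Everything needed to synthesize one movie.

    Defaults mirror the acquisition geometry of the recordings this
    generator emulates: 100 x 100 pixels over 17 mm x 17 mm (0.17 mm/pixel)
    at 3000 frames/s.  ``source`` is one of the four pacing edges
    (top / bottom / left / right) or a ``(row, col)`` point.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    pixel_size_mm: float = 0.17
    frame_rate_hz: float = 3000.0
    n_frames: int = 1500
    base_speed_mps: float = 0.5
    patches: tuple[Patch, ...] = ()
    block_segments: tuple[tuple[tuple[float, float], tuple[float, float]], ...] = ()
    source: str | tuple[int, int] = "left"
    upstroke_ms: float = 2.0
    apd_ms: float = 100.0
    noise_sd: float = 0.05
    drift_per_s: float = 0.1
    inactive_border_px: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8 x 8")
        if self.pixel_size_mm <= 0 or self.frame_rate_hz <= 0 or self.n_frames < 3:
            raise ValueError("pixel size, frame rate and frame count must be positive")
        if self.base_speed_mps <= 0 or any(p.speed_mps <= 0 for p in self.patches):
            raise ValueError("all conduction speeds must be positive")
        if self.upstroke_ms <= 0 or self.apd_ms <= 0:
            raise ValueError("upstroke_ms and apd_ms must be positive")
        if isinstance(self.source, str):
            if self.source not in EDGE_SOURCES:
                raise ValueError(f"edge source must be one of {EDGE_SOURCES}")
        else:
            r, c = self.source
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise ValueError("point source lies outside the grid")

    def speed_field(self) -> np.ndarray:
        """Per-pixel conduction speed in m/s (base speed plus overrides)."""
        speed = np.full((self.grid_rows, self.grid_cols), self.base_speed_mps)
        for p in self.patches:
            speed[p.footprint(self.grid_rows, self.grid_cols)] = p.speed_mps
        return speed

    def tissue_mask(self) -> np.ndarray:
        mask = np.ones((self.grid_rows, self.grid_cols), dtype=bool)
        b = self.inactive_border_px
        if b > 0:
            mask[:] = False
            mask[b:-b, b:-b] = True
        return mask


@dataclass
class GroundTruth:
    """Per-pixel truth emitted alongside a synthetic movie."""

    lat_ms: np.ndarray  # NaN outside tissue; +inf where the front never arrived
    speed_mps: np.ndarray
    sc_mask: np.ndarray  # speed < SC threshold, within tissue
    tissue: np.ndarray
    flagged: np.ndarray  # front never arrived, or arrived too late for the movie
    component_count: int
    component_areas_mm2: list[float]
    sc_threshold_mps: float = SC_THRESHOLD_MPS


# ---------------------------------------------------------------------------
# Eikonal front propagation
# ---------------------------------------------------------------------------

_ALL_OFFSETS = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, -1), (1, -1), (-1, 1)]


def _segments_cross(p1, p2, q1, q2) -> bool:
    """True if open segments p1-p2 and q1-q2 properly intersect (or touch)."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(q1, q2, p1), orient(q1, q2, p2)
    d3, d4 = orient(p1, p2, q1), orient(p1, p2, q2)
    if ((d1 > 0) != (d2 > 0) or d1 == 0 or d2 == 0) and (
        (d3 > 0) != (d4 > 0) or d3 == 0 or d4 == 0
    ):
        # conservative: also count collinear touching as a crossing
        def on_seg(a, b, c):
            return (
                min(a[0], b[0]) <= c[0] <= max(a[0], b[0])
                and min(a[1], b[1]) <= c[1] <= max(a[1], b[1])
            )

        if d1 == 0 and not on_seg(q1, q2, p1):
            return False
        if d2 == 0 and not on_seg(q1, q2, p2):
            return False
        if d3 == 0 and not on_seg(p1, p2, q1):
            return False
        if d4 == 0 and not on_seg(p1, p2, q2):
            return False
        return True
    return False


def _blocked_edges(shape, segments) -> dict[tuple[int, int, int, int], bool]:
    """Set of pixel-center edges cut by any block segment.

    Keys are (r1, c1, r2, c2) in both orientations.  Segments are given in
    pixel coordinates (row, col).
    """
    blocked: dict[tuple[int, int, int, int], bool] = {}
    if not segments:
        return blocked
    rows, cols = shape
    for seg in segments:
        q1, q2 = seg
        rmin = int(np.floor(min(q1[0], q2[0]) - 1.5))
        rmax = int(np.ceil(max(q1[0], q2[0]) + 1.5))
        cmin = int(np.floor(min(q1[1], q2[1]) - 1.5))
        cmax = int(np.ceil(max(q1[1], q2[1]) + 1.5))
        for r in range(max(0, rmin), min(rows, rmax + 1)):
            for c in range(max(0, cmin), min(cols, cmax + 1)):
                for dr, dc in _ALL_OFFSETS:
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < rows and 0 <= c2 < cols):
                        continue
                    if _segments_cross((r, c), (r2, c2), q1, q2):
                        blocked[(r, c, r2, c2)] = True
                        blocked[(r2, c2, r, c)] = True
    return blocked


def _solve_quadratic(ta: float, tb: float, hf: float) -> float:
    """First-arrival update from two orthogonal upwind neighbors at cost hf."""
    if ta > tb:
        ta, tb = tb, ta
    if np.isinf(ta):
        return np.inf
    if tb - ta >= hf or np.isinf(tb):
        return ta + hf
    return 0.5 * (ta + tb) + 0.5 * np.sqrt(2.0 * hf * hf - (tb - ta) ** 2)


def eikonal_travel_time(
    speed_mps: np.ndarray,
    pixel_size_mm: float,
    sources: np.ndarray,
    tissue: np.ndarray | None = None,
    block_segments=(),
) -> np.ndarray:
    """First-arrival times (ms) of a front propagating through ``speed_mps``.

    Fast marching with upwind quadratic updates over both the axis-aligned
    stencil (spacing h) and the 45-degree rotated stencil (spacing h*sqrt2),
    so all 8 neighbors inform each update.  The local travel cost is
    pixel_size / speed; edges crossing a block segment are severed.
    Unreached pixels keep +inf; non-tissue pixels are NaN.
    """
    speed = np.asarray(speed_mps, dtype=float)
    rows, cols = speed.shape
    if tissue is None:
        tissue = np.ones_like(speed, dtype=bool)
    blocked = _blocked_edges(speed.shape, block_segments)
    # ms per pixel step: h [mm] / v [m/s] = h/v ms (1 m/s == 1 mm/ms)
    cost = pixel_size_mm / speed
    diag_cost = cost * np.sqrt(2.0)

    t = np.full(speed.shape, np.inf)
    t[sources & tissue] = 0.0
    done = np.zeros(speed.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = [
        (0.0, int(r), int(c)) for r, c in np.argwhere(sources & tissue)
    ]
    heapq.heapify(heap)

    def neighbor_time(r, c, dr, dc):
        r2, c2 = r + dr, c + dc
        if not (0 <= r2 < rows and 0 <= c2 < cols) or not tissue[r2, c2]:
            return np.inf
        if blocked and (r, c, r2, c2) in blocked:
            return np.inf
        return t[r2, c2]

    while heap:
        tv, r, c = heapq.heappop(heap)
        if done[r, c] or tv > t[r, c]:
            continue
        done[r, c] = True
        for dr, dc in _ALL_OFFSETS:
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < rows and 0 <= c2 < cols):
                continue
            if done[r2, c2] or not tissue[r2, c2]:
                continue
            if blocked and (r2, c2, r, c) in blocked:
                continue
            hf, hfd = cost[r2, c2], diag_cost[r2, c2]
            ta1 = min(neighbor_time(r2, c2, 0, 1), neighbor_time(r2, c2, 0, -1))
            ta2 = min(neighbor_time(r2, c2, 1, 0), neighbor_time(r2, c2, -1, 0))
            td1 = min(neighbor_time(r2, c2, 1, 1), neighbor_time(r2, c2, -1, -1))
            td2 = min(neighbor_time(r2, c2, 1, -1), neighbor_time(r2, c2, -1, 1))
            cand = min(
                _solve_quadratic(ta1, ta2, hf),
                _solve_quadratic(td1, td2, hfd),
            )
            if cand < t[r2, c2]:
                t[r2, c2] = cand
                heapq.heappush(heap, (cand, r2, c2))
    t[~tissue] = np.nan
    return t


def _source_mask(spec: SceneSpec) -> np.ndarray:
    src = np.zeros((spec.grid_rows, spec.grid_cols), dtype=bool)
    tissue = spec.tissue_mask()
    if isinstance(spec.source, str):
        b = spec.inactive_border_px
        if spec.source == "left":
            src[:, b] = True
        elif spec.source == "right":
            src[:, spec.grid_cols - 1 - b] = True
        elif spec.source == "top":
            src[b, :] = True
        else:  # bottom
            src[spec.grid_rows - 1 - b, :] = True
    else:
        r, c = spec.source
        src[r, c] = True
    src &= tissue
    if not src.any():
        raise ValueError("source lies entirely outside the tissue")
    return src


def _ap_trace(t_ms: np.ndarray, lat_ms: float, upstroke_ms: float, apd_ms: float) -> np.ndarray:
    """Action-potential-shaped trace: sigmoid upstroke whose maximum slope
    falls exactly at ``lat_ms``, a plateau of ``apd_ms``, then exponential
    recovery."""
    tau_up = upstroke_ms / 4.394  # logistic 10-90% rise time = upstroke_ms
    up = 1.0 / (1.0 + np.exp(-(t_ms - lat_ms) / tau_up))
    tau_rec = max(5.0, apd_ms / 5.0)
    after = t_ms - (lat_ms + apd_ms)
    rec = np.where(after > 0, np.exp(-np.maximum(after, 0.0) / tau_rec), 1.0)
    return up * rec


def make_movie(spec: SceneSpec) -> tuple[VoltageMovie, GroundTruth]:
    """Synthesize a movie and its ground truth from a scene description.

    True activation times come from :func:`eikonal_travel_time` on the
    scene's speed field; traces, drift and noise are layered on top.
    Pixels the front never reaches (or reaches after the movie ends) are
    flagged in the ground truth rather than silently truncated.
    """
    spec.validate()
    speed = spec.speed_field()
    tissue = spec.tissue_mask()
    sources = _source_mask(spec)
    lat = eikonal_travel_time(
        speed, spec.pixel_size_mm, sources, tissue, spec.block_segments
    )

    duration_ms = 1000.0 * spec.n_frames / spec.frame_rate_hz
    finite = np.isfinite(lat)
    too_late = finite & (lat + spec.upstroke_ms > duration_ms)
    unreached = tissue & ~finite
    flagged = unreached | too_late

    t_ms = np.arange(spec.n_frames) * 1000.0 / spec.frame_rate_hz
    data = np.zeros((spec.n_frames, spec.grid_rows, spec.grid_cols))
    # start upstrokes a few time constants into the movie so the sigmoid
    # foot is fully recorded
    lat_offset_ms = 3.0 * spec.upstroke_ms
    act = tissue & finite
    rr, cc = np.nonzero(act)
    for r, c in zip(rr, cc):
        data[:, r, c] = _ap_trace(
            t_ms, lat[r, c] + lat_offset_ms, spec.upstroke_ms, spec.apd_ms
        )

    rng = np.random.default_rng(spec.seed)
    if spec.drift_per_s != 0.0:
        data += spec.drift_per_s * (t_ms[:, None, None] / 1000.0)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    sc_mask = tissue & (speed < SC_THRESHOLD_MPS)
    n_comp, areas = _true_components(sc_mask, spec.pixel_size_mm)
    truth_lat = np.where(tissue, lat + lat_offset_ms, np.nan)
    truth = GroundTruth(
        lat_ms=truth_lat,
        speed_mps=np.where(tissue, speed, np.nan),
        sc_mask=sc_mask,
        tissue=tissue,
        flagged=flagged,
        component_count=n_comp,
        component_areas_mm2=areas,
    )
    movie = VoltageMovie(data, spec.frame_rate_hz, spec.pixel_size_mm)
    return movie, truth


def _true_components(sc_mask: np.ndarray, pixel_size_mm: float) -> tuple[int, list[float]]:
    """4-connected components of the true SC mask, single pixels excluded."""
    from scipy import ndimage

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(sc_mask, structure=structure)
    if n == 0:
        return 0, []
    sizes = np.bincount(labels.ravel())[1:]
    px_area = pixel_size_mm**2
    areas = [float(s * px_area) for s in sizes if s > 1]
    return len(areas), areas


# ---------------------------------------------------------------------------
# Clustered study tables
# ---------------------------------------------------------------------------

POSITIONS = ("top", "left", "bottom", "right")
TRAINS = ("S1", "S2")
CLASSES = ("control", "persistentAF")


@dataclass
class EffectSpec:
    """Additive fixed effects for one outcome.

    Every term defaults to zero; keys of the interaction dicts are
    ``(class, train)`` / ``(class, position)`` tuples.
    """

    grand_mean: float = 0.0
    class_effects: dict = field(default_factory=dict)
    train_effects: dict = field(default_factory=dict)
    position_effects: dict = field(default_factory=dict)
    class_train: dict = field(default_factory=dict)
    class_position: dict = field(default_factory=dict)

    def cell_mean(self, cls: str, train: str, position: str) -> float:
        return (
            self.grand_mean
            + self.class_effects.get(cls, 0.0)
            + self.train_effects.get(train, 0.0)
            + self.position_effects.get(position, 0.0)
            + self.class_train.get((cls, train), 0.0)
            + self.class_position.get((cls, position), 0.0)
        )


@dataclass
class StudyDesign:
    """A clustered factorial design: animals x pacing positions x trains.

    The default sizes mirror the study layout this package analyzes:
    7 animals (3 control, 4 persistent AF) x 4 positions x 2 trains with
    one missing cell = 55 observations.
    """

    n_animals_per_class: dict = field(
        default_factory=lambda: {"control": 3, "persistentAF": 4}
    )
    positions: tuple[str, ...] = POSITIONS
    trains: tuple[str, ...] = TRAINS
    effects: dict = field(default_factory=lambda: {"percent_sc": EffectSpec(grand_mean=20.0)})
    animal_sd: float = 5.0
    resid_sd: float = 5.0
    missing: tuple[tuple[str, str, str], ...] = ()
    seed: int = 0

    def animal_ids(self) -> list[tuple[str, str]]:
        ids = []
        for cls in CLASSES:
            for i in range(self.n_animals_per_class.get(cls, 0)):
                ids.append((f"{cls}_{i + 1}", cls))
        return ids

    def validate(self) -> None:
        if self.animal_sd < 0 or self.resid_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.animal_ids() or not self.positions or not self.trains or not self.effects:
            raise ValueError("empty design")
        ids = {a for a, _ in self.animal_ids()}
        for animal, position, train in self.missing:
            if animal not in ids or position not in self.positions or train not in self.trains:
                raise ValueError(f"missing cell ({animal}, {position}, {train}) not in design")


def make_study_table(design: StudyDesign) -> pd.DataFrame:
    """Simulate the clustered outcome table for a study design.

    One row per retained (animal, position, train) cell and outcome;
    outcome value = fixed-effect cell mean + animal random intercept
    (sd ``animal_sd``) + residual (sd ``resid_sd``).  Fully reproducible
    from ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    animals = design.animal_ids()
    dropped = set(design.missing)
    rows = []
    for outcome, eff in design.effects.items():
        re = {a: rng.normal(0.0, design.animal_sd) for a, _ in animals}
        for animal, cls in animals:
            for position in design.positions:
                for train in design.trains:
                    if (animal, position, train) in dropped:
                        continue
                    value = (
                        eff.cell_mean(cls, train, position)
                        + re[animal]
                        + rng.normal(0.0, design.resid_sd)
                    )
                    rows.append(
                        {
                            "animal": animal,
                            "cls": cls,
                            "position": position,
                            "train": train,
                            "outcome": outcome,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def save_ground_truth(truth: GroundTruth, spec: SceneSpec, out_dir: str | Path) -> None:
    """Write ground truth as CSV grids plus a JSON sidecar with the spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "true_lat_ms.csv", truth.lat_ms, delimiter=",", fmt="%.6g")
    np.savetxt(out_dir / "true_speed_mps.csv", truth.speed_mps, delimiter=",", fmt="%.6g")
    np.savetxt(out_dir / "true_sc_mask.csv", truth.sc_mask.astype(int), delimiter=",", fmt="%d")
    sidecar = {
        "scene_spec": asdict(spec),
        "sc_threshold_mps": truth.sc_threshold_mps,
        "component_count": truth.component_count,
        "component_areas_mm2": truth.component_areas_mm2,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2, default=str))
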