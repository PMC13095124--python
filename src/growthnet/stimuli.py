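"""Procedural stimuli for curve-tracing and object-parsing tasks.

Stimuli live on an ``N×N`` grid of cells; each cell renders as a 3×3 pixel
block, so a 36×36 grid yields a 108×108 RGB image.  Curve cells are green,
the fixation cue is a red cell on one end of the target curve, and each
figure carries exactly one blue marker cell (the candidate eye-movement
targets).  The task is to select a pixel of the blue cell on the figure
containing the red cue.

The module also produces the per-scale "unambiguous region" labels used to
supervise the scale-selection pathway: a receptive field at scale ``l``
covers a ``3^(l-1) × 3^(l-1)`` block of cells and is labelled positive when
its content permits grouping at that scale (a single connected collinear
run of one curve, or the homogeneous interior of one object).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

CELL_PX = 3
N_SCALES = 4

# direction steps: right, left, down, up
_STEPS = ((0, 1), (0, -1), (1, 0), (-1, 0))


class GenerationError(RuntimeError):
    """Raised when a stimulus cannot be placed within the retry budget."""


@dataclass(frozen=True)
class GridCurve:
    """An ordered, self-avoiding, 4-connected path of grid cells."""

    cells: tuple
    color_head: Optional[str] = None   # "red" cue on cells[0], or None
    color_tail: bool = False           # blue marker on cells[-1]

    def __post_init__(self):
        cells = tuple(tuple(c) for c in self.cells)
        object.__setattr__(self, "cells", cells)
        if len(cells) < 2:
            raise ValueError("curve length must be >= 2 cells")
        if len(set(cells)) != len(cells):
            raise ValueError("curve revisits a cell")
        for (r0, c0), (r1, c1) in zip(cells, cells[1:]):
            if abs(r0 - r1) + abs(c0 - c1) != 1:
                raise ValueError("consecutive cells must be 4-connected")

    def __len__(self):
        return len(self.cells)


@dataclass(frozen=True)
class BottleneckSpec:
    """Geometry of a bottleneck stimulus: gap width and probe positions."""

    gap_cells: int
    probe_cells_near: tuple
    probe_cells_far: tuple
    bottleneck_cols: tuple = ()


@dataclass
class Stimulus:
    """A rendered task image plus its exact generating geometry.

    ``target``/``distractor`` are :class:`GridCurve` instances for the
    curve-tracing task and boolean ``(N, N)`` cell masks for object parsing.
    """

    image: np.ndarray              # (H, W, 3) float in [0, 1]
    grid_size: int
    cell_px: int
    kind: str                      # "curve" | "object"
    target: object
    distractor: object
    fixation_cell: tuple
    target_cell: tuple
    distractor_cell: tuple
    seed: Optional[int] = None

    def target_cells(self) -> list:
        return _figure_cells(self.target)

    def distractor_cells(self) -> list:
        return _figure_cells(self.distractor)

    @property
    def image_chw(self) -> np.ndarray:
        """Channel-first view used by the network code."""
        return np.ascontiguousarray(self.image.transpose(2, 0, 1))


@dataclass
class GateLabelSet:
    """Binary 'unambiguous RF' maps, one per scale, at gate resolution."""

    labels: list = field(default_factory=list)   # list of bool arrays

    def __getitem__(self, scale: int) -> np.ndarray:
        """1-based scale index, matching hidden-layer numbering."""
        return self.labels[scale - 1]

    def __len__(self):
        return len(self.labels)


def _figure_cells(fig) -> list:
    if isinstance(fig, GridCurve):
        return list(fig.cells)
    rs, cs = np.nonzero(np.asarray(fig))
    return list(zip(rs.tolist(), cs.tolist()))


def pyramid_resolutions(h: int, n_scales: int = N_SCALES) -> list:
    """Pixel resolution of layers 0..n (iterated ceil-divide by 3)."""
    res = [h]
    for _ in range(n_scales):
        res.append(-(-res[-1] // 3))
    return res


# ----------------------------------------------------------------- rendering

def render(grid_size: int, green, red, blue, cell_px: int = CELL_PX) -> np.ndarray:
    """Render cell sets to an (H, W, 3) image; later colors overwrite."""
    h = grid_size * cell_px
    img = np.zeros((h, h, 3))
    for cells, ch in ((green, 1), (red, 0), (blue, 2)):
        for (r, c) in cells:
            block = (slice(r * cell_px, (r + 1) * cell_px),
                     slice(c * cell_px, (c + 1) * cell_px))
            img[block + (slice(None),)] = 0.0
            img[block + (ch,)] = 1.0
    return img


def extract_cells(image: np.ndarray, cell_px: int = CELL_PX) -> dict:
    """Invert :func:`render`: recover the colored cell sets from an image."""
    h = image.shape[0] // cell_px
    w = image.shape[1] // cell_px
    out = {"red": set(), "green": set(), "blue": set()}
    names = {0: "red", 1: "green", 2: "blue"}
    for r in range(h):
        for c in range(w):
            block = image[r * cell_px:(r + 1) * cell_px,
                          c * cell_px:(c + 1) * cell_px]
            for ch, name in names.items():
                if block[..., ch].min() == 1.0:
                    out[name].add((r, c))
    return out


def _render_curves(grid_size: int, target: GridCurve, distractor: GridCurve,
                   seed=None) -> Stimulus:
    green = list(target.cells) + list(distractor.cells)
    red = [target.cells[0]]
    blue = [target.cells[-1], distractor.cells[-1]]
    img = render(grid_size, green, red, blue)
    return Stimulus(
        image=img, grid_size=grid_size, cell_px=CELL_PX, kind="curve",
        target=target, distractor=distractor,
        fixation_cell=target.cells[0], target_cell=target.cells[-1],
        distractor_cell=distractor.cells[-1], seed=seed)


# -------------------------------------------------------------- curve pairs

def _self_avoiding_walk(rng, grid_size: int, length: int, forbidden) -> Optional[list]:
    """One attempt at a self-avoiding 4-connected walk avoiding `forbidden`."""
    free = [(r, c) for r in range(grid_size) for c in range(grid_size)
            if (r, c) not in forbidden]
    if not free:
        return None
    start = free[rng.integers(len(free))]
    path = [start]
    occupied = {start}
    while len(path) < length:
        r, c = path[-1]
        options = []
        for dr, dc in _STEPS:
            nxt = (r + dr, c + dc)
            if (0 <= nxt[0] < grid_size and 0 <= nxt[1] < grid_size
                    and nxt not in occupied and nxt not in forbidden):
                options.append(nxt)
        if not options:
            return None
        nxt = options[rng.integers(len(options))]
        path.append(nxt)
        occupied.add(nxt)
    return path


def _dilate(cells, grid_size: int, radius: int = 1) -> set:
    """Chebyshev dilation: the cells plus a `radius`-wide ring around them."""
    out = set()
    for (r, c) in cells:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                out.add((r + dr, c + dc))
    return out


def generate_curve_pair(grid_size: int, length: int, rng_seed: int,
                        max_tries: int = 400) -> Stimulus:
    """Two non-touching random curves; red cue on the target, blue markers
    on the free ends of both curves.

    Curves are self-avoiding 4-connected walks kept at Chebyshev distance
    >= 2 from each other (at least one empty cell between the figures).
    Deterministic given ``rng_seed``.
    """
    if length < 2 or length > grid_size * grid_size // 2:
        raise ValueError(f"invalid curve length {length} for grid {grid_size}")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_tries):
        t = _self_avoiding_walk(rng, grid_size, length, forbidden=set())
        if t is None:
            continue
        forbidden = _dilate(t, grid_size)
        d = _self_avoiding_walk(rng, grid_size, length, forbidden)
        if d is None:
            continue
        target = GridCurve(tuple(t), color_head="red", color_tail=True)
        distractor = GridCurve(tuple(d), color_head=None, color_tail=True)
        return _render_curves(grid_size, target, distractor, seed=rng_seed)
    raise GenerationError(
        f"could not place two length-{length} curves on a {grid_size} grid "
        f"after {max_tries} attempts")


# --------------------------------------------------------------- bottleneck

def generate_bottleneck_pair(gap_cells: int, rng_seed: int, grid_size: int = 36,
                             length: int = 24, far_rows: int = 9,
                             bottleneck_width: int = 5):
    """Straight target curve with a distractor that dips toward it.

    The target runs horizontally; the distractor runs parallel at a distance
    of ``far_rows`` rows but approaches to ``gap_cells`` empty cells over a
    ``bottleneck_width``-column bottleneck.  Probe cells on the target curve
    before (near) and behind (far) the bottleneck are recorded.
    """
    if gap_cells < 1:
        raise ValueError("gap_cells must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rt_min, rt_max = 2, grid_size - far_rows - 3
    if rt_max < rt_min or length + 4 > grid_size:
        raise GenerationError("bottleneck geometry does not fit the grid")
    rt = int(rng.integers(rt_min, rt_max + 1))
    rd = rt + far_rows                      # distractor's far row
    rn = rt + gap_cells + 1                 # distractor's near row
    if rn >= rd:
        raise GenerationError("gap too wide for the requested far distance")
    c0 = int(rng.integers(2, grid_size - length - 1))
    c1 = c0 + length - 1
    bx0 = c0 + (length - bottleneck_width) // 2
    bx1 = bx0 + bottleneck_width - 1

    target = [(rt, c) for c in range(c0, c1 + 1)]
    dist = [(rd, c) for c in range(c0, bx0)]
    dist += [(r, bx0) for r in range(rd, rn - 1, -1)]
    dist += [(rn, c) for c in range(bx0 + 1, bx1)]
    dist += [(r, bx1) for r in range(rn, rd + 1)]
    dist += [(rd, c) for c in range(bx1 + 1, c1 + 1)]

    tcurve = GridCurve(tuple(target), color_head="red", color_tail=True)
    dcurve = GridCurve(tuple(dist), color_head=None, color_tail=True)
    stim = _render_curves(grid_size, tcurve, dcurve, seed=rng_seed)
    spec = BottleneckSpec(
        gap_cells=gap_cells,
        probe_cells_near=(rt, max(c0 + 1, bx0 - 2)),
        probe_cells_far=(rt, min(c1 - 1, bx1 + 2)),
        bottleneck_cols=(bx0, bx1))
    return stim, spec


# ------------------------------------------------------------------ objects

def _grow_blob(rng, grid_size: int, n_cells: int, forbidden) -> Optional[np.ndarray]:
    """Grow a filled 4-connected polyomino by random boundary accretion."""
    free = [(r, c) for r in range(grid_size) for c in range(grid_size)
            if (r, c) not in forbidden]
    if not free:
        return None
    start = free[rng.integers(len(free))]
    blob = {start}
    frontier = {start}
    while len(blob) < n_cells:
        candidates = set()
        for (r, c) in frontier:
            for dr, dc in _STEPS:
                nxt = (r + dr, c + dc)
                if (0 <= nxt[0] < grid_size and 0 <= nxt[1] < grid_size
                        and nxt not in blob and nxt not in forbidden):
                    candidates.add(nxt)
        if not candidates:
            return None
        cand = sorted(candidates)
        pick = cand[rng.integers(len(cand))]
        blob.add(pick)
        frontier = {pick} | {c for c in frontier}
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    for (r, c) in blob:
        mask[r, c] = True
    return mask


def generate_object_pair(grid_size: int, rng_seed: int,
                         min_cells: Optional[int] = None,
                         max_cells: Optional[int] = None,
                         max_tries: int = 200) -> Stimulus:
    """Two disjoint filled random objects; red cue inside one, blue markers
    inside both.

    Object sizes default to 2–8 % of the grid area; objects are kept at
    Chebyshev distance >= 2 so no receptive field of any scale can be fully
    covered by two different objects.
    """
    if grid_size < 8:
        raise ValueError("grid_size must be >= 8 for the object task")
    if min_cells is None:
        min_cells = max(4, grid_size * grid_size // 50)
    if max_cells is None:
        max_cells = max(min_cells + 1, grid_size * grid_size // 12)
    if min_cells < 2:
        raise ValueError("objects must exceed one cell (cue and marker must fit)")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_tries):
        n1 = int(rng.integers(min_cells, max_cells + 1))
        n2 = int(rng.integers(min_cells, max_cells + 1))
        m1 = _grow_blob(rng, grid_size, n1, forbidden=set())
        if m1 is None:
            continue
        forb = _dilate(list(zip(*np.nonzero(m1))), grid_size)
        m2 = _grow_blob(rng, grid_size, n2, forb)
        if m2 is None:
            continue
        cells1 = sorted(zip(*np.nonzero(m1)))
        cells2 = sorted(zip(*np.nonzero(m2)))
        cue = cells1[rng.integers(len(cells1))]
        t_marker = cue
        while t_marker == cue:
            t_marker = cells1[rng.integers(len(cells1))]
        d_marker = cells2[rng.integers(len(cells2))]
        green = [c for c in cells1 + cells2 if c not in (cue, t_marker, d_marker)]
        img = render(grid_size, green, [cue], [t_marker, d_marker])
        return Stimulus(
            image=img, grid_size=grid_size, cell_px=CELL_PX, kind="object",
            target=m1, distractor=m2, fixation_cell=tuple(cue),
            target_cell=tuple(t_marker), distractor_cell=tuple(d_marker),
            seed=rng_seed)
    raise GenerationError(
        f"could not place two objects on a {grid_size} grid after {max_tries} tries")


# --------------------------------------------------------------- gate labels

def _rf_cell_block(scale: int, i: int, j: int) -> tuple:
    """Half-open cell range covered by gate unit (i, j) at `scale`."""
    side = 3 ** (scale - 1)
    return i * side, (i + 1) * side, j * side, (j + 1) * side


def _collinear_run(cells: Sequence) -> bool:
    """True iff the cells form a single contiguous straight row or column."""
    rows = {r for r, _ in cells}
    cols = {c for _, c in cells}
    if len(rows) == 1:
        idx = sorted(c for _, c in cells)
    elif len(cols) == 1:
        idx = sorted(r for r, _ in cells)
    else:
        return False
    return all(b - a == 1 for a, b in zip(idx, idx[1:]))


def _block_reduce(a: np.ndarray, side: int, how: str) -> np.ndarray:
    """Reduce non-overlapping side×side blocks (pad with the identity)."""
    n = a.shape[0]
    m = -(-n // side) * side
    fill = {"sum": 0, "max": -10**9, "min": 10**9}[how]
    ap = np.full((m, m), fill, dtype=a.dtype)
    ap[:n, :n] = a
    b = ap.reshape(m // side, side, m // side, side)
    op = {"sum": np.sum, "max": np.max, "min": np.min}[how]
    return op(b, axis=(1, 3))


def _curve_labels_fast(mask: np.ndarray, other: np.ndarray, side: int) -> np.ndarray:
    """Vectorized per-RF label for one curve mask at one scale.

    A block is positive for this curve iff it contains at least one of its
    cells, none of the other curve's, and the cells form one contiguous
    straight row or column segment (count equals the span of a single line).
    """
    big = 10**6
    rows = np.arange(mask.shape[0])[:, None] * np.ones_like(mask, dtype=int)
    cols = np.arange(mask.shape[1])[None, :] * np.ones_like(mask, dtype=int)
    cnt = _block_reduce(mask.astype(int), side, "sum")
    cnt_o = _block_reduce(other.astype(int), side, "sum")
    rmin = _block_reduce(np.where(mask, rows, big), side, "min")
    rmax = _block_reduce(np.where(mask, rows, -big), side, "max")
    cmin = _block_reduce(np.where(mask, cols, big), side, "min")
    cmax = _block_reduce(np.where(mask, cols, -big), side, "max")
    row_run = (rmin == rmax) & (cnt == cmax - cmin + 1)
    col_run = (cmin == cmax) & (cnt == rmax - rmin + 1)
    return (cnt > 0) & (cnt_o == 0) & (row_run | col_run)


def gate_labels_curve(stim: Stimulus, n_scales: int = N_SCALES) -> GateLabelSet:
    """Positive where all curve cells in the RF form one connected collinear
    run of a single curve; negative for empty RFs and RFs straddling curves.
    """
    if stim.kind != "curve":
        raise ValueError("expected a curve-tracing stimulus")
    n = stim.grid_size
    tmask = np.zeros((n, n), dtype=bool)
    dmask = np.zeros((n, n), dtype=bool)
    for c in stim.target_cells():
        tmask[c] = True
    for c in stim.distractor_cells():
        dmask[c] = True
    h = stim.image.shape[0]
    res = pyramid_resolutions(h, n_scales)
    labels = []
    for scale in range(1, n_scales + 1):
        side = 3 ** (scale - 1)
        lab_t = _curve_labels_fast(tmask, dmask, side)
        lab_d = _curve_labels_fast(dmask, tmask, side)
        lab = np.zeros((res[scale], res[scale]), dtype=bool)
        hs = lab_t.shape[0]
        lab[:hs, :hs] = lab_t | lab_d
        labels.append(lab)
    return GateLabelSet(labels)


def gate_labels_curve_slow(stim: Stimulus, n_scales: int = N_SCALES) -> GateLabelSet:
    """Reference implementation: per-RF geometric predicate (used as the
    oracle for the vectorized version)."""
    if stim.kind != "curve":
        raise ValueError("expected a curve-tracing stimulus")
    tset = set(stim.target_cells())
    dset = set(stim.distractor_cells())
    return _labels_from_predicate(stim, n_scales, lambda block: _curve_rf_label(block, tset, dset))


def _curve_rf_label(block, tset, dset) -> bool:
    r0, r1, c0, c1 = block
    inside_t = [c for c in tset if r0 <= c[0] < r1 and c0 <= c[1] < c1]
    inside_d = [c for c in dset if r0 <= c[0] < r1 and c0 <= c[1] < c1]
    if inside_t and inside_d:
        return False
    inside = inside_t or inside_d
    if not inside:
        return False
    return _collinear_run(inside)


def gate_labels_object(stim: Stimulus, n_scales: int = N_SCALES) -> GateLabelSet:
    """Positive where the RF lies entirely inside a single object."""
    if stim.kind != "object":
        raise ValueError("expected an object-parsing stimulus")
    masks = (np.asarray(stim.target), np.asarray(stim.distractor))
    n = masks[0].shape[0]
    h = stim.image.shape[0]
    res = pyramid_resolutions(h, n_scales)
    labels = []
    for scale in range(1, n_scales + 1):
        side = 3 ** (scale - 1)
        m = -(-n // side) * side
        lab = np.zeros((res[scale], res[scale]), dtype=bool)
        for mask in masks:
            mp = np.zeros((m, m), dtype=bool)   # out-of-grid counts as background
            mp[:n, :n] = mask
            full = mp.reshape(m // side, side, m // side, side).all(axis=(1, 3))
            lab[:full.shape[0], :full.shape[1]] |= full
        labels.append(lab)
    return GateLabelSet(labels)


def gate_labels_object_slow(stim: Stimulus, n_scales: int = N_SCALES) -> GateLabelSet:
    """Reference per-RF predicate (oracle for the vectorized version)."""
    if stim.kind != "object":
        raise ValueError("expected an object-parsing stimulus")
    masks = (np.asarray(stim.target), np.asarray(stim.distractor))

    def pred(block):
        r0, r1, c0, c1 = block
        nn = masks[0].shape[0]
        if r1 > nn or c1 > nn:
            return False    # RF extends into the padded border
        return any(m[r0:r1, c0:c1].all() for m in masks)

    return _labels_from_predicate(stim, n_scales, pred)


def _labels_from_predicate(stim: Stimulus, n_scales: int, pred) -> GateLabelSet:
    h = stim.image.shape[0]
    res = pyramid_resolutions(h, n_scales)
    labels = []
    for scale in range(1, n_scales + 1):
        hl = res[scale]
        lab = np.zeros((hl, hl), dtype=bool)
        for i in range(hl):
            for j in range(hl):
                lab[i, j] = pred(_rf_cell_block(scale, i, j))
        labels.append(lab)
    return GateLabelSet(labels)


# -------------------------------------------------------------- persistence

def save_stimulus(stim: Stimulus, png_path, json_path) -> None:
    from PIL import Image

    Image.fromarray((stim.image * 255).astype(np.uint8)).save(png_path)
    as_ints = lambda c: [int(c[0]), int(c[1])]
    geom = {
        "grid_size": int(stim.grid_size), "cell_px": int(stim.cell_px),
        "kind": stim.kind, "seed": None if stim.seed is None else int(stim.seed),
        "fixation_cell": as_ints(stim.fixation_cell),
        "target_cell": as_ints(stim.target_cell),
        "distractor_cell": as_ints(stim.distractor_cell),
        "target_cells": [as_ints(c) for c in stim.target_cells()],
        "distractor_cells": [as_ints(c) for c in stim.distractor_cells()],
    }
    with open(json_path, "w") as fh:
        json.dump(geom, fh)


def load_stimulus(png_path, json_path) -> Stimulus:
    from PIL import Image

    img = np.asarray(Image.open(png_path), dtype=float) / 255.0
    with open(json_path) as fh:
        geom = json.load(fh)
    n = geom["grid_size"]
    if geom["kind"] == "curve":
        target = GridCurve(tuple(tuple(c) for c in geom["target_cells"]),
                           color_head="red", color_tail=True)
        distractor = GridCurve(tuple(tuple(c) for c in geom["distractor_cells"]),
                               color_tail=True)
    else:
        target = np.zeros((n, n), dtype=bool)
        distractor = np.zeros((n, n), dtype=bool)
        for c in geom["target_cells"]:
            target[tuple(c)] = True
        for c in geom["distractor_cells"]:
            distractor[tuple(c)] = True
    return Stimulus(image=img, grid_size=n, cell_px=geom["cell_px"],
                    kind=geom["kind"], target=target, distractor=distractor,
                    fixation_cell=tuple(geom["fixation_cell"]),
                    target_cell=tuple(geom["target_cell"]),
                    distractor_cell=tuple(geom["distractor_cell"]),
                    seed=geom.get("seed"))


def save_dataset(stimuli: Sequence[Stimulus], path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for i, s in enumerate(stimuli):
            g = fh.create_group(f"stimulus_{i:05d}")
            g.create_dataset("image", data=(s.image * 255).astype(np.uint8),
                             compression="gzip")
            g.attrs["kind"] = s.kind
            g.attrs["grid_size"] = s.grid_size
            g.attrs["fixation_cell"] = s.fixation_cell
            g.attrs["target_cell"] = s.target_cell
            g.attrs["distractor_cell"] = s.distractor_cell
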