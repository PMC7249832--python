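"""Mosaic stitching by phase correlation.

Only the central z-stack frame of each site is composited, and only the
central region of each tile appears in the final image — tile edges (which
carry the worst optical quality) are used solely for alignment.  Pairwise
translations between grid-adjacent tiles are measured by phase correlation
on their nominal overlap regions; a global least-squares solve over the
offset graph (anchored at the first tile) turns these into tile positions,
robust to any single bad pair.  Pairs whose correlation is too weak fall
back to the nominal offset and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from .camera import to_gray
from .scanning import Tile, TileSet


@dataclass
class MosaicResult:
    image: np.ndarray
    recovered_offsets_px: dict[tuple[int, int], tuple[float, float]]  # grid idx -> (row, col)
    crop_margin_fraction: float
    flagged_pairs: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)


def _nominal_positions_px(tiles: list[Tile], pitch_nm: float) -> dict[tuple[int, int], np.ndarray]:
    """Tile top-left positions (row, col) from nominal stage coordinates."""
    xs = np.array([t.nominal_xy_nm[0] for t in tiles])
    ys = np.array([t.nominal_xy_nm[1] for t in tiles])
    pos = {}
    for t in tiles:
        col = (t.nominal_xy_nm[0] - xs.min()) / pitch_nm
        row = (ys.max() - t.nominal_xy_nm[1]) / pitch_nm  # stage +y is up, rows go down
        pos[t.grid_index] = np.array([row, col])
    return pos


def _measure_pair_offset(
    img_a: np.ndarray,
    img_b: np.ndarray,
    nominal_delta: np.ndarray,
    max_error: float,
) -> tuple[np.ndarray, bool]:
    """Measured (row, col) displacement of tile b relative to tile a.

    The nominal displacement selects the overlap windows; phase correlation
    on those windows refines it.  Returns (delta, ok).
    """
    h, w = img_a.shape
    dr, dc = nominal_delta
    r0a, r1a = int(max(dr, 0)), int(min(h, h + dr))
    c0a, c1a = int(max(dc, 0)), int(min(w, w + dc))
    ov_a = img_a[r0a:r1a, c0a:c1a]
    r0b, r1b = int(max(-dr, 0)), int(min(h, h - dr))
    c0b, c1b = int(max(-dc, 0)), int(min(w, w - dc))
    ov_b = img_b[r0b:r1b, c0b:c1b]
    hh = min(ov_a.shape[0], ov_b.shape[0])
    ww = min(ov_a.shape[1], ov_b.shape[1])
    if hh < 8 or ww < 8:
        return nominal_delta, False
    ov_a, ov_b = ov_a[:hh, :ww], ov_b[:hh, :ww]
    # Integer shift by masked (overlap-normalized) cross-correlation.  Plain
    # correlation is biased toward zero lag here: the image is dominated by
    # features much wider than the expected shift, so the unnormalized
    # correlation surface is nearly flat and the larger overlap area at zero
    # lag wins.  The masked variant normalizes by the overlap at each lag.
    mask = np.ones(ov_a.shape, dtype=bool)
    coarse, _, _ = phase_cross_correlation(
        ov_a, ov_b, reference_mask=mask, moving_mask=mask, overlap_ratio=0.5
    )
    coarse = np.array(coarse, dtype=float)
    if np.max(np.abs(coarse)) > 0.25 * min(hh, ww):
        return nominal_delta, False
    # Sub-pixel refinement on the integer-aligned overlaps; at sub-pixel lags
    # the zero-lag bias is negligible.
    ir, ic = int(coarse[0]), int(coarse[1])
    ra = ov_a[max(ir, 0) : hh + min(ir, 0), max(ic, 0) : ww + min(ic, 0)]
    rb = ov_b[max(-ir, 0) : hh - max(ir, 0), max(-ic, 0) : ww - max(ic, 0)]
    fine = np.zeros(2)
    if min(ra.shape) >= 8:
        f, _, _ = phase_cross_correlation(ra, rb, upsample_factor=10, normalization=None)
        if np.max(np.abs(f)) <= 1.5:
            fine = np.array(f, dtype=float)
    # quality gate: normalized correlation of the aligned overlaps
    za, zb = ra - ra.mean(), rb - rb.mean()
    denom = np.sqrt((za**2).sum() * (zb**2).sum())
    corr = float((za * zb).sum() / denom) if denom > 0 else 0.0
    if corr < 1.0 - max_error:
        return nominal_delta, False
    return nominal_delta + coarse + fine, True


def stitch_tiles(
    tileset: TileSet | list[Tile],
    crop_margin_fraction: float = 0.25,
    max_correlation_error: float = 0.9,
) -> MosaicResult:
    """Register and composite the central frames of a tile scan.

    ``crop_margin_fraction`` is the fraction of each tile's width/height
    discarded on every side before compositing; the discarded margin must be
    covered by the scan overlap for the mosaic to be gap-free.
    """
    tiles = tileset.central_tiles() if isinstance(tileset, TileSet) else list(tiles_or_central(tileset))
    if not tiles:
        raise ValueError("no tiles to stitch")
    pitch = tiles[0].frame.pixel_pitch_nm
    grays = {t.grid_index: to_gray(t.frame.pixels) for t in tiles}
    nominal = _nominal_positions_px(tiles, pitch)
    index = {t.grid_index: n for n, t in enumerate(tiles)}
    h, w = next(iter(grays.values())).shape

    if len(tiles) == 1:
        only = tiles[0]
        crop = _central_crop(grays[only.grid_index], crop_margin_fraction)
        return MosaicResult(
            image=crop.astype(np.uint8),
            recovered_offsets_px={only.grid_index: (0.0, 0.0)},
            crop_margin_fraction=crop_margin_fraction,
        )

    # measure offsets between grid-adjacent pairs
    edges = []  # (idx_a, idx_b, delta_rowcol)
    flagged = []
    for t in tiles:
        gi, gj = t.grid_index
        for nb in ((gi + 1, gj), (gi, gj + 1)):
            if nb not in grays:
                continue
            nom = nominal[nb] - nominal[t.grid_index]
            delta, ok = _measure_pair_offset(
                grays[t.grid_index], grays[nb], nom, max_correlation_error
            )
            if not ok:
                flagged.append((t.grid_index, nb))
            edges.append((index[t.grid_index], index[nb], delta))

    # global positions by least squares on p_b - p_a = delta, anchored at tile 0
    n = len(tiles)
    rows_eq = len(edges) + 1
    A = np.zeros((rows_eq, n))
    b_r = np.zeros(rows_eq)
    b_c = np.zeros(rows_eq)
    for e, (ia, ib, delta) in enumerate(edges):
        A[e, ia] = -1.0
        A[e, ib] = 1.0
        b_r[e] = delta[0]
        b_c[e] = delta[1]
    A[-1, 0] = 1.0
    anchor = nominal[tiles[0].grid_index]
    b_r[-1] = anchor[0]
    b_c[-1] = anchor[1]
    pr, *_ = np.linalg.lstsq(A, b_r, rcond=None)
    pc, *_ = np.linalg.lstsq(A, b_c, rcond=None)
    positions = {t.grid_index: np.array([pr[index[t.grid_index]], pc[index[t.grid_index]]]) for t in tiles}

    # composite central crops at the solved positions
    mr = int(round(crop_margin_fraction * h))
    mc = int(round(crop_margin_fraction * w))
    crop_h, crop_w = h - 2 * mr, w - 2 * mc
    placements = {
        gi: np.rint(p + np.array([mr, mc])).astype(int) for gi, p in positions.items()
    }
    r_min = min(p[0] for p in placements.values())
    c_min = min(p[1] for p in placements.values())
    r_max = max(p[0] for p in placements.values()) + crop_h
    c_max = max(p[1] for p in placements.values()) + crop_w
    mosaic = np.zeros((r_max - r_min, c_max - c_min), dtype=np.uint8)
    for t in tiles:
        p = placements[t.grid_index] - np.array([r_min, c_min])
        crop = _central_crop(grays[t.grid_index], crop_margin_fraction)
        mosaic[p[0] : p[0] + crop_h, p[1] : p[1] + crop_w] = np.clip(
            np.rint(crop), 0, 255
        ).astype(np.uint8)

    return MosaicResult(
        image=mosaic,
        recovered_offsets_px={gi: tuple(p) for gi, p in positions.items()},
        crop_margin_fraction=crop_margin_fraction,
        flagged_pairs=flagged,
    )


def _central_crop(img: np.ndarray, margin_fraction: float) -> np.ndarray:
    h, w = img.shape
    mr = int(round(margin_fraction * h))
    mc = int(round(margin_fraction * w))
    return img[mr : h - mr, mc : w - mc]


def tiles_or_central(tiles: list[Tile]) -> list[Tile]:
    central = [t for t in tiles if t.is_central]
    return central or tiles
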