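"""Gold-particle detection on replica images.

The automated detector is multi-scale dark-blob detection: the image is
inverted, a scale-normalised Laplacian-of-Gaussian response is computed over
a scale band set by the expected particle diameter and its tolerance, local
maxima above a relative response threshold are collected and greedily
non-maximum-suppressed at the minimum separation.  Localisation is refined
to sub-pixel precision by a local centre of mass of the response, which the
nm-scale cluster statistics downstream rely on.

A seeded semi-automated mode (:func:`refine_seeded`) snaps operator-supplied
approximate positions to the nearest response maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .raster import from_integer


@dataclass(frozen=True)
class DetectionParams:
    expected_diameter_nm: float = 10.0
    diameter_tolerance: float = 0.4  # +/- fraction of the expected diameter
    response_threshold: float = 0.15  # relative blob response in (0, 1)
    min_separation_nm: Optional[float] = None  # defaults to expected diameter
    n_scales: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.response_threshold < 1:
            raise ValueError("response_threshold must be in (0, 1)")
        if not 0 <= self.diameter_tolerance < 1:
            raise ValueError("diameter_tolerance must be in [0, 1)")
        if self.min_separation_nm is not None and self.min_separation_nm <= 0:
            raise ValueError("min_separation_nm must be positive")

    @property
    def separation_nm(self) -> float:
        return self.min_separation_nm or self.expected_diameter_nm


def _response_stack(img: np.ndarray, nm_per_px: float, params: DetectionParams):
    """Scale-normalised LoG responses of the inverted image."""
    inverted = 1.0 - from_integer(img)
    r_px = 0.5 * params.expected_diameter_nm / nm_per_px
    lo = r_px * (1 - params.diameter_tolerance) / np.sqrt(2)
    hi = r_px * (1 + params.diameter_tolerance) / np.sqrt(2)
    sigmas = np.linspace(max(lo, 0.5), max(hi, 0.6), params.n_scales)
    stack = np.stack(
        [-(s**2) * ndimage.gaussian_laplace(inverted, s) for s in sigmas]
    )
    return stack, sigmas


def _subpixel(resp: np.ndarray, row: int, col: int, win: int = 2):
    """Centre of mass of the positive response in a window around a peak."""
    h, w = resp.shape
    r0, r1 = max(row - win, 0), min(row + win + 1, h)
    c0, c1 = max(col - win, 0), min(col + win + 1, w)
    patch = np.clip(resp[r0:r1, c0:c1], 0.0, None)
    total = patch.sum()
    if total <= 0:
        return float(row), float(col)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return float((patch * yy).sum() / total), float((patch * xx).sum() / total)


def _greedy_nms(df: pd.DataFrame, separation_nm: float) -> pd.DataFrame:
    """Keep strongest detections first, suppressing closer-than-separation."""
    if df.empty:
        return df
    order = df.sort_values(
        ["response", "y_nm", "x_nm"], ascending=[False, True, True]
    ).reset_index(drop=True)
    xy = order[["x_nm", "y_nm"]].to_numpy(float)
    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    alive = np.ones(len(xy), bool)
    for i in range(len(xy)):
        if not alive[i]:
            continue
        for j in tree.query_ball_point(xy[i], separation_nm):
            if j > i:
                alive[j] = False
    return order[alive].reset_index(drop=True)


def _deterministic_kmeans(
    pts: np.ndarray, weights: np.ndarray, k: int, n_iter: int = 20
) -> np.ndarray:
    """Weighted Lloyd iterations with farthest-point initialisation.

    Fully deterministic: the first centre is the heaviest point (ties by
    coordinate order), subsequent centres maximise distance to the chosen
    set.  Used to place split detections inside merged blobs.
    """
    order = np.lexsort((pts[:, 1], pts[:, 0], -weights))
    centers = [pts[order[0]]]
    while len(centers) < k:
        d = np.min(
            [np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) for c in centers], axis=0
        )
        centers.append(pts[np.argmax(d)])
    centers = np.array(centers, float)
    for _ in range(n_iter):
        d = np.stack(
            [np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) for c in centers]
        )
        lab = d.argmin(axis=0)
        for j in range(k):
            sel = lab == j
            if sel.any():
                w = weights[sel]
                centers[j] = (pts[sel] * w[:, None]).sum(axis=0) / w.sum()
    return centers


def _split_merged(
    det: pd.DataFrame,
    norm_img: np.ndarray,
    resp_max: np.ndarray,
    nm_per_px: float,
    params: DetectionParams,
    origin_nm: tuple[float, float],
) -> pd.DataFrame:
    """Resolve physically overlapping particles that blur into one blob.

    Gold disks closer than the particle diameter merge into a single dark
    component with no interior intensity minimum, so peak detection alone
    undercounts them.  Dark-mask connected components whose area implies
    more particles than were detected inside are re-populated with that
    many deterministically-placed centroids.
    """
    if det.empty:
        return det
    bg = float(np.median(norm_img))
    depth = bg - float(norm_img.min())
    if depth < 0.15:  # no appreciable dark foreground; nothing to split
        return det
    mask = norm_img < bg - 0.5 * depth
    labels, n_comp = ndimage.label(mask)
    if n_comp == 0:
        return det
    r_px = 0.5 * params.expected_diameter_nm / nm_per_px
    a1 = np.pi * r_px**2  # area of one particle's dark disk
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))

    col = ((det["x_nm"] - origin_nm[0]) / nm_per_px - 0.5).round().astype(int)
    row = ((det["y_nm"] - origin_nm[1]) / nm_per_px - 0.5).round().astype(int)
    h, w = labels.shape
    det_comp = np.full(len(det), 0)
    inb = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    det_comp[inb] = labels[row[inb], col[inb]]

    keep = np.ones(len(det), bool)
    extra_rows = []
    inv = np.clip(bg - norm_img, 0.0, None)
    # a lone disk's mask area stays within ~8% of a1 even under shading, so
    # components are split once they exceed 1.35 disk areas
    for comp in np.flatnonzero(areas >= 1.35 * a1) + 1:
        n_est = min(int(np.floor(areas[comp - 1] / a1 + 0.65)), 12)
        members = np.flatnonzero(det_comp == comp)
        if n_est <= len(members):
            continue
        rr, cc = np.nonzero(labels == comp)
        pts = np.column_stack([cc + 0.5, rr + 0.5]).astype(float)
        centers = _deterministic_kmeans(pts, inv[rr, cc], n_est)
        response = float(resp_max[rr, cc].max())
        keep[members] = False
        for cx, cy in centers:
            extra_rows.append(
                {
                    "x_nm": origin_nm[0] + cx * nm_per_px,
                    "y_nm": origin_nm[1] + cy * nm_per_px,
                    "radius_nm": r_px * nm_per_px,
                    "response": response,
                }
            )
    if not extra_rows:
        return det
    return pd.concat(
        [det[keep], pd.DataFrame(extra_rows)], ignore_index=True
    )


def detect_particles(
    img: np.ndarray,
    nm_per_px: float,
    params: DetectionParams = DetectionParams(),
    *,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Detect dark gold particles; returns x_nm, y_nm, radius_nm, response.

    Deterministic for a fixed image and parameters.  A constant (saturated)
    image yields an empty table.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("image must be single-channel")
    if img.max() == img.min():
        return pd.DataFrame(columns=["x_nm", "y_nm", "radius_nm", "response"])

    stack, sigmas = _response_stack(img, nm_per_px, params)
    resp_max = stack.max(axis=0)
    scale_idx = stack.argmax(axis=0)

    min_dist_px = max(int(round(params.separation_nm / nm_per_px / 2)), 1)
    peaks = peak_local_max(
        resp_max,
        min_distance=min_dist_px,
        threshold_abs=params.response_threshold,
        exclude_border=False,
    )
    rows = []
    for r, c in peaks:
        rr, cc = _subpixel(resp_max, r, c)
        sigma = sigmas[scale_idx[r, c]]
        rows.append(
            {
                "x_nm": origin_nm[0] + (cc + 0.5) * nm_per_px,
                "y_nm": origin_nm[1] + (rr + 0.5) * nm_per_px,
                "radius_nm": sigma * np.sqrt(2) * nm_per_px,
                "response": float(resp_max[r, c]),
            }
        )
    det = pd.DataFrame(rows, columns=["x_nm", "y_nm", "radius_nm", "response"])
    det = _greedy_nms(det, params.separation_nm)
    return _split_merged(
        det, from_integer(img), resp_max, nm_per_px, params, origin_nm
    )


def refine_seeded(
    img: np.ndarray,
    nm_per_px: float,
    seeds_nm: Sequence[tuple[float, float]],
    params: DetectionParams = DetectionParams(),
    *,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Snap approximate seed points to local response maxima.

    Seeds in flat regions (response below threshold everywhere within the
    expected diameter) are dropped; coincident snaps are merged by the
    minimum-separation rule.
    """
    if len(seeds_nm) == 0:
        return pd.DataFrame(columns=["x_nm", "y_nm", "radius_nm", "response"])
    img = np.asarray(img)
    stack, sigmas = _response_stack(img, nm_per_px, params)
    resp_max = stack.max(axis=0)
    scale_idx = stack.argmax(axis=0)
    h, w = resp_max.shape
    search_px = max(int(np.ceil(params.expected_diameter_nm / nm_per_px)), 1)

    rows = []
    for x_nm, y_nm in seeds_nm:
        c = (x_nm - origin_nm[0]) / nm_per_px - 0.5
        r = (y_nm - origin_nm[1]) / nm_per_px - 0.5
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed ({x_nm}, {y_nm}) outside image")
        r0, r1 = max(int(r) - search_px, 0), min(int(r) + search_px + 1, h)
        c0, c1 = max(int(c) - search_px, 0), min(int(c) + search_px + 1, w)
        window = resp_max[r0:r1, c0:c1]
        pr, pc = np.unravel_index(np.argmax(window), window.shape)
        pr, pc = pr + r0, pc + c0
        if resp_max[pr, pc] < params.response_threshold:
            continue  # flat region: seed dropped
        rr, cc = _subpixel(resp_max, pr, pc)
        rows.append(
            {
                "x_nm": origin_nm[0] + (cc + 0.5) * nm_per_px,
                "y_nm": origin_nm[1] + (rr + 0.5) * nm_per_px,
                "radius_nm": sigmas[scale_idx[pr, pc]] * np.sqrt(2) * nm_per_px,
                "response": float(resp_max[pr, pc]),
            }
        )
    det = pd.DataFrame(rows, columns=["x_nm", "y_nm", "radius_nm", "response"])
    return _greedy_nms(det, params.separation_nm)


@dataclass(frozen=True)
class MatchReport:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    rmse_nm: float
    pairs: tuple[tuple[int, int], ...]  # (detection index, truth index)


def match_to_truth(
    detections: pd.DataFrame, truth: pd.DataFrame, gate_nm: float = 10.0
) -> MatchReport:
    """One-to-one matching maximising matches within the distance gate."""
    det_xy = detections[["x_nm", "y_nm"]].to_numpy(float)
    tru_xy = truth[["x_nm", "y_nm"]].to_numpy(float)
    nd, nt = len(det_xy), len(tru_xy)
    if nd == 0 or nt == 0:
        return MatchReport(0, nd, nt, 0.0 if nt else 1.0, 0.0 if nd else 1.0, 0.0, ())
    d = np.hypot(
        det_xy[:, None, 0] - tru_xy[None, :, 0],
        det_xy[:, None, 1] - tru_xy[None, :, 1],
    )
    big = 1e9
    cost = np.where(d <= gate_nm, d, big)
    ri, ci = linear_sum_assignment(cost)
    pairs = tuple(
        (int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= gate_nm
    )
    tp = len(pairs)
    rmse = (
        float(np.sqrt(np.mean([d[i, j] ** 2 for i, j in pairs]))) if pairs else 0.0
    )
    return MatchReport(
        tp=tp,
        fp=nd - tp,
        fn=nt - tp,
        recall=tp / nt,
        precision=tp / nd,
        rmse_nm=rmse,
        pairs=pairs,
    )
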