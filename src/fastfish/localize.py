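"""Spot detection, subpixel localization, co-localization and trace extraction.

The analysis chain of a two-channel CoSMoS movie: find diffraction-limited
spots frame by frame, localize each by a symmetric 2D Gaussian fit of its
5 x 5 pixel neighbourhood, pool the localizations of a whole video into
"blobs" (clusters on a 1-pixel 2D histogram), pair blobs across channels by
nearest neighbour to build the co-localization plot, select the loci inside
the central peak, and read out background-subtracted intensity traces from
small ROIs at those loci.

Pixel convention: pixel centres at integer coordinates, x rightward (column),
y downward (row); subpixel positions are floats in the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "SpotFit",
    "Blob",
    "ColocPlot",
    "detect_spots",
    "fit_gaussian_2d",
    "cluster_blobs",
    "colocalization_offsets",
    "select_active",
    "active_by_frames",
    "extract_trace",
]


@dataclass
class SpotFit:
    """Result of a single 2D Gaussian spot fit."""

    frame: int
    x: float
    y: float
    amplitude: float
    offset: float
    sigma: float
    residual: float
    ok: bool


@dataclass
class Blob:
    """A cluster of localizations interpreted as one molecule position."""

    x: float
    y: float
    count: int
    frames: np.ndarray


@dataclass
class ColocPlot:
    """Nearest-neighbour displacements between two blob sets."""

    dx: np.ndarray
    dy: np.ndarray
    pair_index: np.ndarray      # index of nearest query blob per reference
    hist: np.ndarray
    hist_edges: np.ndarray
    sigma: float | None = None  # width of the fitted central peak, px

    @property
    def n_pairs(self) -> int:
        return self.dx.size


def detect_spots(
    frame: np.ndarray,
    min_snr: float = 5.0,
    psf_sigma: float = 1.0,
) -> list[tuple[int, int]]:
    """Candidate peak pixels (y, x) above the noise floor.

    The frame is lightly smoothed with a Gaussian matched to the PSF, the
    background is taken as the image median and the noise as the scaled
    median absolute deviation; local maxima exceeding
    ``median + min_snr * noise`` survive non-maximum suppression within one
    PSF radius.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a single 2D frame")
    smooth = ndimage.gaussian_filter(img, psf_sigma)
    bg = np.median(smooth)
    noise = 1.4826 * np.median(np.abs(smooth - bg))
    if noise == 0:
        noise = np.finfo(float).tiny
    radius = max(1, int(round(2 * psf_sigma)))
    maxima = ndimage.maximum_filter(smooth, size=2 * radius + 1)
    mask = (smooth == maxima) & (smooth > bg + min_snr * noise)
    ys, xs = np.nonzero(mask)
    return list(zip(ys.tolist(), xs.tolist()))


def _gauss2d(params, xx, yy):
    a, x0, y0, sigma, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)) + b


def fit_gaussian_2d(
    roi: np.ndarray,
    frame: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> SpotFit:
    """Least-squares fit of a symmetric 2D Gaussian + offset to a 5x5 patch.

    *origin* is the (y, x) of the patch's top-left pixel in the full frame;
    the returned position is in full-frame coordinates.  Fits that do not
    converge, or converge to a non-positive amplitude, are flagged rejected.
    """
    roi = np.asarray(roi, dtype=float)
    h, w = roi.shape
    yy, xx = np.mgrid[0:h, 0:w]
    b0 = roi.min()
    a0 = roi.max() - b0
    p0 = [a0 if a0 > 0 else 1.0, (w - 1) / 2, (h - 1) / 2, 1.0, b0]

    def resid(p):
        return (_gauss2d(p, xx, yy) - roi).ravel()

    try:
        sol = optimize.least_squares(
            resid,
            p0,
            bounds=([0, -1, -1, 0.3, -np.inf], [np.inf, w, h, max(h, w), np.inf]),
            max_nfev=200,
        )
    except ValueError:
        sol = None
    ok = sol is not None and sol.success and sol.x[0] > 0 and a0 > 0
    if sol is None:
        a, x0, y0, sigma, b, res = 0.0, np.nan, np.nan, np.nan, 0.0, np.inf
    else:
        a, x0, y0, sigma, b = sol.x
        res = float(np.sqrt(np.mean(sol.fun**2)))
    oy, ox = origin
    return SpotFit(
        frame=frame,
        x=float(x0 + ox),
        y=float(y0 + oy),
        amplitude=float(a),
        offset=float(b),
        sigma=float(sigma),
        residual=res,
        ok=bool(ok),
    )


def localize_frame(
    frame_img: np.ndarray,
    frame_index: int = 0,
    min_snr: float = 5.0,
    psf_sigma: float = 1.0,
    roi_half: int = 2,
) -> list[SpotFit]:
    """Detect and Gaussian-fit every spot of one frame (5x5 ROIs)."""
    fits = []
    h, w = frame_img.shape
    for y, x in detect_spots(frame_img, min_snr, psf_sigma):
        if not (roi_half <= y < h - roi_half and roi_half <= x < w - roi_half):
            continue
        roi = frame_img[y - roi_half : y + roi_half + 1, x - roi_half : x + roi_half + 1]
        fit = fit_gaussian_2d(roi, frame=frame_index, origin=(y - roi_half, x - roi_half))
        if fit.ok:
            fits.append(fit)
    return fits


def cluster_blobs(localizations: np.ndarray, frames: np.ndarray | None = None) -> list[Blob]:
    """Group (x, y) localizations into blobs on a 1-pixel 2D histogram.

    Occupied 1-px bins joined by 8-connectivity form one blob; the blob
    position is the centroid of its member localizations.
    """
    pts = np.atleast_2d(np.asarray(localizations, dtype=float))
    if pts.size == 0:
        raise ValueError("no localizations to cluster")
    if frames is None:
        frames = np.zeros(len(pts), dtype=int)
    bins = np.floor(pts + 0.5).astype(int)  # pixel containing each localization
    xmin, ymin = bins.min(axis=0)
    grid = np.zeros(
        (bins[:, 1].max() - ymin + 1, bins[:, 0].max() - xmin + 1), dtype=bool
    )
    grid[bins[:, 1] - ymin, bins[:, 0] - xmin] = True
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    blob_ids = labels[bins[:, 1] - ymin, bins[:, 0] - xmin]
    blobs = []
    for lab in range(1, n + 1):
        member = blob_ids == lab
        blobs.append(
            Blob(
                x=float(pts[member, 0].mean()),
                y=float(pts[member, 1].mean()),
                count=int(member.sum()),
                frames=np.unique(np.asarray(frames)[member]),
            )
        )
    return blobs


def colocalization_offsets(
    reference_blobs: list[Blob],
    query_blobs: list[Blob],
    hist_range: float = 8.0,
    bin_width: float = 0.25,
) -> ColocPlot:
    """Nearest-query displacement (dx, dy) for every reference blob."""
    if not reference_blobs:
        raise ValueError("empty reference blob set")
    if not query_blobs:
        raise ValueError("empty query blob set")
    ref = np.array([[b.x, b.y] for b in reference_blobs])
    qry = np.array([[b.x, b.y] for b in query_blobs])
    d2 = ((ref[:, None, :] - qry[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    delta = qry[nearest] - ref
    edges = np.arange(-hist_range, hist_range + bin_width, bin_width)
    hist, _, _ = np.histogram2d(delta[:, 0], delta[:, 1], bins=[edges, edges])
    return ColocPlot(
        dx=delta[:, 0], dy=delta[:, 1], pair_index=nearest, hist=hist, hist_edges=edges
    )


def _fit_central_peak(coloc: ColocPlot) -> tuple[float, float]:
    """2D Gaussian fit of the histogram around (0, 0); returns (sigma, peak)."""
    edges = coloc.hist_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(centers, centers, indexing="ij")
    h = coloc.hist
    a0 = h.max() - np.median(h)
    p0 = [max(a0, 1.0), 0.0, 0.0, 0.5, float(np.median(h))]

    def resid(p):
        return (_gauss2d(p, xx, yy) - h).ravel()

    sol = optimize.least_squares(
        resid,
        p0,
        bounds=([0, -2, -2, 0.05, 0], [np.inf, 2, 2, 5.0, np.inf]),
        max_nfev=400,
    )
    if not sol.success or sol.x[0] <= 0:
        raise RuntimeError("no discernible central co-localization peak")
    return float(sol.x[3]), float(sol.x[0])


def select_active(coloc: ColocPlot, radius_sd: float = 2.0) -> np.ndarray:
    """Indices of reference blobs inside the central co-localization peak.

    The central peak of the (dx, dy) histogram is fitted with a 2D Gaussian
    to estimate its width sigma; references whose offset magnitude is at most
    ``radius_sd * sigma`` are selected (~40 nm at the default 2 sigma and
    200 nm pixels).  Raises when no central peak stands out — compare against
    a randomized control in that case.
    """
    sigma, amp = _fit_central_peak(coloc)
    bg = np.median(coloc.hist)
    if amp < 3 * max(bg, 1.0):
        raise RuntimeError(
            "central co-localization peak not prominent; "
            "compare against a randomized control"
        )
    coloc.sigma = sigma
    r = np.hypot(coloc.dx, coloc.dy)
    return np.nonzero(r <= radius_sd * sigma)[0]


def active_by_frames(coloc_flags: np.ndarray, min_frames: int = 5) -> bool:
    """A locus is active when co-localized in >= min_frames cumulative frames."""
    return int(np.sum(np.asarray(coloc_flags, dtype=bool))) >= min_frames


def extract_trace(stack: np.ndarray, locus: tuple[float, float], roi_size: int = 3) -> np.ndarray:
    """Background-subtracted intensity time series at a locus.

    Per frame: mean of the inner ``roi_size x roi_size`` pixel block centred
    on the locus, minus the mean of the one-pixel perimeter ring around it.
    """
    if roi_size not in (3, 5):
        raise ValueError("roi_size must be 3 or 5")
    stack = np.asarray(stack, dtype=float)
    nf, h, w = stack.shape
    x, y = locus
    cx, cy = int(round(x)), int(round(y))
    half = roi_size // 2
    outer = half + 1
    if not (outer <= cy < h - outer and outer <= cx < w - outer):
        raise ValueError(f"locus {locus} too close to the frame edge for roi {roi_size}")
    block = stack[:, cy - outer : cy + outer + 1, cx - outer : cx + outer + 1]
    inner = block[:, 1:-1, 1:-1]
    inner_sum = inner.sum(axis=(1, 2))
    ring_sum = block.sum(axis=(1, 2)) - inner_sum
    ring_n = block.shape[1] * block.shape[2] - roi_size**2
    return inner_sum / roi_size**2 - ring_sum / ring_n
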