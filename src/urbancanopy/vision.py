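"""Canopy-architecture analysis of upward-looking RGB frames.

The analysis chain mirrors upward-looking cover photography: binarize the
blue channel at the valley between the foliage peak (dark, canopy seen
against the sky) and the sky peak (bright), subdivide the binary mask into a
5x5 grid of sub-images, classify large gaps (sub-images dominated by sky),
and derive foliage projective cover ``ff``, crown cover ``fc`` and crown
porosity ``phi``.  Leaf area index follows Beer-Lambert light extinction,

    LAI = -fc * ln(phi) / k,

with extinction coefficient ``k`` (0.5 for tall trees).  The zenith clumping
index

    Omega(0) = (1 - phi) * ln(1 - ff) / (ff * ln(phi))

corrects LAI for non-random foliage dispersion; effective LAI is
``LAIe = LAI * Omega(0)``.  Omega(0) = 1 indicates random dispersion,
values below 1 indicate clumped foliage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "CanopyFrame",
    "BinaryCanopyMask",
    "GapAnalysisResult",
    "CanopyArchitecture",
    "InvalidFrameError",
    "blue_histogram",
    "find_valley_threshold",
    "binarize",
    "gap_analysis",
    "compute_lai",
    "compute_clumping_index",
    "compute_laie",
    "canopy_architecture",
    "analyze_frame",
]

#: channel order in stored frames (RGB); the blue channel drives binarization
BLUE_CHANNEL = 2


class InvalidFrameError(ValueError):
    """Raised for frames that cannot enter the vision pipeline."""


@dataclass
class CanopyFrame:
    """One upward-looking visible frame.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3), integer intensities 0-255
    timestamp : capture time (UTC), optional
    position : (lat, lon) in degrees, optional
    """

    pixels: np.ndarray
    timestamp: datetime | None = None
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidFrameError(
                f"expected an H x W x 3 RGB array, got shape {px.shape}"
            )
        if px.shape[0] < 5 or px.shape[1] < 5:
            raise InvalidFrameError(
                f"frame {px.shape[0]}x{px.shape[1]} too small for 5x5 gap analysis"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryCanopyMask:
    """Binarized frame: True = canopy/foliage, False = sky/gap."""

    mask: np.ndarray
    threshold_used: int
    method: str  # "valley" | "otsu_fallback"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class GapAnalysisResult:
    """Pixel ledgers and cover fractions for one frame.

    ``tp`` total pixels, ``tg`` total gap (sky) pixels, ``lg`` pixels inside
    large gaps (sub-images with sky fraction above ``large_gap_fraction``).
    ``ff = 1 - tg/tp``, ``fc = 1 - lg/tp``, ``phi = 1 - ff/fc``.
    """

    tp: int
    tg: int
    lg: int
    ff: float
    fc: float
    phi: float
    degenerate: bool = False
    reason: str = ""


@dataclass
class CanopyArchitecture:
    """Beer-Lambert LAI, zenith clumping index and effective LAI."""

    lai: float
    omega0: float
    laie: float
    k: float
    degenerate: bool = False
    reason: str = ""


def blue_histogram(frame: CanopyFrame, blue_channel: int = BLUE_CHANNEL) -> np.ndarray:
    """256-bin intensity histogram of the frame's blue channel."""
    blue = frame.pixels[:, :, blue_channel]
    return np.bincount(blue.ravel().astype(np.int64), minlength=256)[:256]


def _smooth(hist: np.ndarray, width: int) -> np.ndarray:
    # moving average, 'same' length; edge bins average over a shrunken window
    kernel = np.ones(width) / width
    return np.convolve(hist.astype(float), kernel, mode="same")


def _plateau_peaks(s: np.ndarray) -> list[tuple[int, float]]:
    """Local maxima of ``s`` including plateaus and edges.

    A plateau of equal values strictly above both neighbours is one peak at
    its midpoint (rounded down).  Edges count: the array is padded with -1.
    Returns (position, height) pairs in increasing position order.
    """
    t = np.concatenate(([-1.0], s, [-1.0]))
    peaks: list[tuple[int, float]] = []
    i = 1
    while i < len(t) - 1:
        if t[i] > t[i - 1]:
            j = i
            while j + 1 < len(t) - 1 and t[j + 1] == t[i]:
                j += 1
            if t[j + 1] < t[i]:
                peaks.append(((i - 1 + j - 1) // 2, float(t[i])))
            i = j + 1
        else:
            i += 1
    return peaks


def find_valley_threshold(
    hist: np.ndarray, smoothing_width: int = 5
) -> tuple[int, str]:
    """Threshold at the histogram valley between foliage and sky peaks.

    The histogram is smoothed with a fixed-width moving average, its two
    highest local maxima are taken as the foliage (dark) and sky (bright)
    peaks, and the threshold is placed at the minimum strictly between them;
    ties resolve to the midpoint of the tied run, rounding down.  When fewer
    than two peaks survive smoothing (unimodal scene) Otsu's method is used
    instead; the returned tag records which route fired.

    Returns
    -------
    (threshold, method) with method ``"valley"`` or ``"otsu_fallback"``.
    """
    hist = np.asarray(hist)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if hist.sum() == 0:
        raise ValueError("empty histogram")

    s = _smooth(hist, smoothing_width)
    peaks = _plateau_peaks(s)
    if len(peaks) >= 2:
        # two dominant peaks = greatest smoothed height; ties -> lower bin
        dominant = sorted(peaks, key=lambda p: (-p[1], p[0]))[:2]
        p1, p2 = sorted(pos for pos, _ in dominant)
        if p2 - p1 >= 2:
            interior = s[p1 + 1 : p2]
            lo = np.flatnonzero(interior == interior.min()) + p1 + 1
            return int((lo[0] + lo[-1]) // 2), "valley"

    centers = np.arange(256)
    return int(round(float(threshold_otsu(hist=(hist, centers))))), "otsu_fallback"


def binarize(
    frame: CanopyFrame,
    threshold: int,
    method: str = "valley",
    invert: bool = False,
    blue_channel: int = BLUE_CHANNEL,
) -> BinaryCanopyMask:
    """Classify pixels as canopy (blue <= threshold) or sky.

    Canopy occupies the darker first peak in upward shots against bright
    sky; ``invert=True`` flips the polarity for scenes where foliage is
    brighter than the background.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    blue = frame.pixels[:, :, blue_channel]
    mask = blue > threshold if invert else blue <= threshold
    return BinaryCanopyMask(mask=mask, threshold_used=int(threshold), method=method)


def _block_edges(n: int, blocks: int) -> list[int]:
    # integer division; remainder pixels merge into the final block
    step = n // blocks
    return [i * step for i in range(blocks)] + [n]


def gap_analysis(
    mask: BinaryCanopyMask | np.ndarray,
    grid: tuple[int, int] = (5, 5),
    large_gap_fraction: float = 0.75,
    strict: bool = True,
) -> GapAnalysisResult:
    """Subdivide the mask into a grid and ledger gap pixels.

    A sub-image is a large gap when its sky fraction exceeds
    ``large_gap_fraction`` (strictly, by default: "over 75% of sky").
    Sub-image boundaries come from integer division with remainder pixels
    merged into the last row/column of blocks, so the partition is
    exhaustive and deterministic.
    """
    m = mask.mask if isinstance(mask, BinaryCanopyMask) else np.asarray(mask, bool)
    rows, cols = grid
    h, w = m.shape
    if h < rows or w < cols:
        raise ValueError(f"mask {h}x{w} smaller than {rows}x{cols} grid")

    sky = ~m
    tp = int(m.size)
    tg = int(sky.sum())

    lg = 0
    redges, cedges = _block_edges(h, rows), _block_edges(w, cols)
    for r0, r1 in zip(redges[:-1], redges[1:]):
        for c0, c1 in zip(cedges[:-1], cedges[1:]):
            block = sky[r0:r1, c0:c1]
            n_sky = int(block.sum())
            frac = n_sky / block.size
            is_large = frac > large_gap_fraction if strict else frac >= large_gap_fraction
            if is_large:
                lg += n_sky

    ff = 1.0 - tg / tp
    fc = 1.0 - lg / tp
    degenerate, reason = False, ""
    if fc == 0.0:
        phi = math.nan
        degenerate, reason = True, "entire image is large gap (fc = 0)"
    else:
        phi = 1.0 - ff / fc
        if tg == 0:
            degenerate, reason = True, "all-canopy frame (phi = 0, LAI unbounded)"
        elif ff == 0.0:
            degenerate, reason = True, "all-sky frame (no foliage)"
    return GapAnalysisResult(tp=tp, tg=tg, lg=lg, ff=ff, fc=fc, phi=phi,
                             degenerate=degenerate, reason=reason)


def compute_lai(ga: GapAnalysisResult, k: float = 0.5) -> float:
    """Beer-Lambert leaf area index, ``-fc * ln(phi) / k``.

    ``phi = 1`` (fully porous crown) gives 0; ``phi = 0`` gives ``inf``
    (flagged degenerate upstream rather than raised, so a survey never
    aborts on one saturated frame).
    """
    if k <= 0:
        raise ValueError(f"extinction coefficient k must be positive, got {k}")
    if not ga.fc > 0 or math.isnan(ga.phi):
        return math.nan
    if ga.phi == 0.0:
        return math.inf
    if ga.phi == 1.0:
        return 0.0
    return -ga.fc * math.log(ga.phi) / k


def compute_clumping_index(ga: GapAnalysisResult) -> float:
    """Zenith clumping index Omega(0) = (1-phi) ln(1-ff) / (ff ln(phi)).

    Equals 1 for randomly dispersed foliage filling the crown area
    (fc = 1 so phi = 1 - ff and the logarithms cancel); below 1 for
    clumped canopies.  Undefined (NaN) when ff or phi hits {0, 1}.
    """
    if not (0.0 < ga.ff < 1.0) or math.isnan(ga.phi) or not (0.0 < ga.phi < 1.0):
        return math.nan
    return (1.0 - ga.phi) * math.log(1.0 - ga.ff) / (ga.ff * math.log(ga.phi))


def compute_laie(lai: float, omega0: float) -> float:
    """Effective LAI: the clumping-corrected product ``LAI * Omega(0)``."""
    return lai * omega0


def canopy_architecture(ga: GapAnalysisResult, k: float = 0.5) -> CanopyArchitecture:
    """Derive LAI, Omega(0) and LAIe from a gap-analysis ledger, with flags."""
    lai = compute_lai(ga, k=k)
    omega0 = compute_clumping_index(ga)
    degenerate = ga.degenerate or not math.isfinite(lai) or not math.isfinite(omega0)
    reason = ga.reason
    if degenerate and not reason:
        reason = "LAI or clumping index undefined for this frame"
    laie = compute_laie(lai, omega0) if not degenerate else math.nan
    return CanopyArchitecture(lai=lai, omega0=omega0, laie=laie, k=k,
                              degenerate=degenerate, reason=reason)


def analyze_frame(
    frame: CanopyFrame,
    k: float = 0.5,
    grid: tuple[int, int] = (5, 5),
    large_gap_fraction: float = 0.75,
    smoothing_width: int = 5,
    invert: bool = False,
    blue_channel: int = BLUE_CHANNEL,
) -> tuple[BinaryCanopyMask, GapAnalysisResult, CanopyArchitecture]:
    """Full vision chain for one frame: threshold, binarize, gap-analyse."""
    hist = blue_histogram(frame, blue_channel=blue_channel)
    threshold, method = find_valley_threshold(hist, smoothing_width=smoothing_width)
    mask = binarize(frame, threshold, method=method, invert=invert,
                    blue_channel=blue_channel)
    ga = gap_analysis(mask, grid=grid, large_gap_fraction=large_gap_fraction)
    arch = canopy_architecture(ga, k=k)
    return mask, ga, arch
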