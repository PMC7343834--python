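"""Semi-automatic plaque segmentation.

The procedure mirrors operator-guided extraction of hyper-intense deposits
from a tomographic volume:

1. each seed (a circular ROI on the coronal plane plus a slice range)
   becomes a cylindrical volume of interest; all cylinders are unioned;
2. the pooled gray-value histogram of VOI voxels is bimodal — one peak for
   tissue background, one for plaque material; the threshold is placed at
   the valley (minimum count) between the two peaks, falling back to Otsu's
   threshold when no two peaks survive prominence filtering;
3. voxels above the threshold are grouped into 26-connected components and
   components at or below a minimum physical volume (default 150 um^3) are
   discarded as too small to be plaques.

Both inequalities are strict (``gray > threshold``, ``volume > min_volume``)
so object counts are exactly reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from ._exceptions import ConfigurationError, DomainError
from .volume_io import LabelMap, SeedROI, Volume

log = logging.getLogger(__name__)

#: Minimum retained plaque volume in um^3 (structures at or below are dropped).
DEFAULT_MIN_VOLUME_UM3 = 150.0

HIST_BINS = 256
SMOOTH_WIDTH = 5             # moving-average width, bins
PEAK_PROMINENCE_FRAC = 0.01  # of the max smoothed count
VALLEY_DEPTH_FRAC = 0.75     # valley must dip below this fraction of the weaker peak


@dataclass
class VOIMask:
    """Union of cylindrical VOIs, with per-seed provenance."""

    mask: np.ndarray                      # bool, congruent with the Volume
    seeds: list[SeedROI] = field(default_factory=list)
    #: per-seed boolean masks are not stored (memory); provenance is recorded
    #: as the index of the first seed claiming each voxel, -1 elsewhere.
    provenance: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ThresholdResult:
    """Outcome of bimodal-histogram threshold selection."""

    bin_edges: np.ndarray
    counts: np.ndarray
    background_peak: float
    plaque_peak: float
    threshold: float
    bimodal_found: bool
    method: str = "valley"  # "valley" or "otsu-fallback"

    def to_dict(self) -> dict:
        return {
            "background_peak": float(self.background_peak),
            "plaque_peak": float(self.plaque_peak),
            "threshold": float(self.threshold),
            "bimodal_found": bool(self.bimodal_found),
            "method": self.method,
        }


def build_voi_mask(seeds: list[SeedROI], volume: Volume) -> VOIMask:
    """Union of one cylinder per seed, clipped to the grid.

    A voxel belongs to a seed's cylinder iff the in-plane distance from its
    centre to the seed centre is <= the seed radius and its coronal slice
    lies in the seed's inclusive slice range.  Seeds falling entirely
    outside the grid are skipped with a warning.
    """
    shape = volume.shape
    vs = volume.voxel_size_um
    mask = np.zeros(shape, dtype=bool)
    prov = np.full(shape, -1, dtype=np.int32)
    kept: list[SeedROI] = []
    for si, seed in enumerate(seeds):
        cx, cy = seed.center
        z0, z1 = seed.slice_range
        z0c, z1c = max(z0, 0), min(z1, shape[2] - 1)
        r_vox = seed.radius_um / vs
        i0 = max(int(np.floor(cx - r_vox)), 0)
        i1 = min(int(np.ceil(cx + r_vox)) + 1, shape[0])
        j0 = max(int(np.floor(cy - r_vox)), 0)
        j1 = min(int(np.ceil(cy + r_vox)) + 1, shape[1])
        if z0c > z1c or i0 >= i1 or j0 >= j1:
            warnings.warn(f"seed {si} lies fully outside the grid; skipped", stacklevel=2)
            continue
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        disc = ((ii - cx) ** 2 + (jj - cy) ** 2) * vs**2 <= seed.radius_um**2
        sub = mask[i0:i1, j0:j1, z0c : z1c + 1]
        cyl = disc[..., None] & np.ones(z1c - z0c + 1, dtype=bool)
        psub = prov[i0:i1, j0:j1, z0c : z1c + 1]
        psub[cyl & (psub < 0)] = si
        sub |= cyl
        kept.append(seed)
    return VOIMask(mask=mask, seeds=list(seeds), provenance=prov)


def find_bimodal_threshold(volume: Volume, voi: VOIMask) -> ThresholdResult:
    """Threshold from the pooled gray histogram of VOI voxels.

    The histogram (256 bins over the VOI gray range) is smoothed by a
    5-bin moving average; peaks need prominence >= 1% of the maximum count.
    With two or more peaks the two most prominent are taken as background
    (lower gray) and plaque (higher gray) and the threshold is the gray
    value of the minimum count between them — on ties, the midpoint of the
    minimal plateau.  Otherwise Otsu's threshold is used and flagged.
    """
    if voi.n_voxels == 0:
        raise DomainError("VOI mask is empty; cannot build a histogram")
    grays = volume.voxels[voi.mask].astype(np.float64)
    lo, hi = float(grays.min()), float(grays.max())
    if lo == hi:
        raise DomainError("VOI has constant gray value; no contrast to threshold")
    counts, edges = np.histogram(grays, bins=HIST_BINS, range=(lo, hi))
    kernel = np.ones(SMOOTH_WIDTH) / SMOOTH_WIDTH
    smooth = np.convolve(counts.astype(np.float64), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])

    # zero-pad so peaks sitting on the histogram edges are detectable
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, props = find_peaks(padded, prominence=PEAK_PROMINENCE_FRAC * smooth.max())
    peaks = peaks - 1
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        p_lo, p_hi = int(top2.min()), int(top2.max())
        valley = smooth[p_lo : p_hi + 1]
        vmin = valley.min()
        # sampling wiggles on a unimodal histogram also pass the prominence
        # filter; only accept bimodality if the valley dips well below the
        # weaker peak
        if vmin < VALLEY_DEPTH_FRAC * min(smooth[p_lo], smooth[p_hi]):
            flat = np.nonzero(valley == vmin)[0] + p_lo
            # midpoint of the minimal plateau (tie rule)
            thr = float(0.5 * (centers[flat[0]] + centers[flat[-1]]))
            return ThresholdResult(
                bin_edges=edges,
                counts=counts,
                background_peak=float(centers[p_lo]),
                plaque_peak=float(centers[p_hi]),
                threshold=thr,
                bimodal_found=True,
                method="valley",
            )
    thr = float(threshold_otsu(grays))
    log.warning("histogram not bimodal; falling back to Otsu threshold %.4g", thr)
    return ThresholdResult(
        bin_edges=edges,
        counts=counts,
        background_peak=float(centers[int(np.argmax(smooth))]),
        plaque_peak=float("nan"),
        threshold=thr,
        bimodal_found=False,
        method="otsu-fallback",
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ConfigurationError(f"connectivity must be 6 or 26, got {connectivity}")


def extract_plaques(
    volume: Volume,
    voi: VOIMask,
    threshold: float,
    min_volume_um3: float = DEFAULT_MIN_VOLUME_UM3,
    connectivity: int = 26,
    max_gray: float | None = None,
) -> LabelMap:
    """Threshold inside the VOI and keep components above the volume filter.

    Foreground voxels satisfy ``gray > threshold`` (optionally also
    ``gray <= max_gray``) and lie inside the VOI mask.  Components are
    26-connected by default; those with physical volume <= ``min_volume_um3``
    are removed.  Surviving labels are renumbered contiguously from 1 in
    order of descending volume.
    """
    vs = volume.voxel_size_um
    fg = voi.mask & (volume.voxels > threshold)
    if max_gray is not None:
        fg &= volume.voxels <= max_gray
    structure = _connectivity_structure(connectivity)
    lab, n = ndimage.label(fg, structure=structure)
    if n == 0:
        return LabelMap(labels=lab.astype(np.int32), voxel_size_um=vs)
    sizes = np.bincount(lab.ravel())[1:]  # voxel counts per label 1..n
    vols = sizes * vs**3
    keep = np.nonzero(vols > min_volume_um3)[0] + 1
    order = keep[np.argsort(vols[keep - 1])[::-1]]  # descending volume
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1)
    return LabelMap(labels=remap[lab], voxel_size_um=vs)
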