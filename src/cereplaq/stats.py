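"""Population statistics for plaque and Purkinje morphometry.

Covers four analyses:

* scalar summaries (mean, sample std, adjusted Fisher-Pearson skewness,
  quantiles) of sphericity or volume samples;
* the elongation inclusion rule ``S < S_mean + S_std`` that keeps only
  objects elongated enough for their main axis to be meaningful;
* a log-normality check of the plaque volume distribution: the empirical
  distribution of log-volumes is compared, via a Kolmogorov-Smirnov
  statistic, against the Gaussian with the *same* mean and standard
  deviation (moment-matched by construction, not an MLE fit);
* axial (undirected) orientation statistics: the mean axis is the principal
  eigenvector of the orientation tensor ``T = (1/n) sum a_i a_i^T``, cone
  semi-angles are percentiles of the angular deviations
  ``arccos |a_i . mean|``, optionally resolved into coordinate planes, and
  a 2D azimuth-elevation histogram counts each axis at both antipodal
  representations (an undirected axis has no sign).

Group differences in sphericity are tested with a two-sided Mann-Whitney U:
sphericity is bounded and skewed, so a rank test is preferred over a t-test.
For two small groups (both n <= 8) the p-value comes from exact enumeration
of all arrangements with midrank tie handling, making tiny-sample results
deterministic; larger groups use the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from ._exceptions import DomainError
from .morphometry import MorphRecord, axis_to_angles, canonicalize_axis

DEFAULT_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.9)
ORIENT_HIST_BIN_DEG = 10.0


@dataclass
class StatsSummary:
    """Moments and quantiles of a scalar sample."""

    n: int
    mean: float
    std: float           # sample std, n-1 denominator
    skewness: float
    quantiles: dict[float, float]
    skewness_flag: bool = False  # std == 0: skewness undefined, reported 0

    @property
    def median(self) -> float:
        return self.quantiles[0.5]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "std": self.std,
            "skewness": self.skewness,
            "skewness_flag": self.skewness_flag,
            "quantiles": {str(q): v for q, v in self.quantiles.items()},
        }


@dataclass
class LogNormalCheck:
    """Log-volume moments and KS distance to the moment-matched Gaussian."""

    n: int
    log_mean: float
    log_std: float
    ks_statistic: float
    hist_bin_edges: np.ndarray
    hist_density: np.ndarray          # empirical log-volume density
    reference_density: np.ndarray     # matched Gaussian pdf at bin centres

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "log_mean": self.log_mean,
            "log_std": self.log_std,
            "ks_statistic": self.ks_statistic,
            "hist_bin_edges": self.hist_bin_edges.tolist(),
            "hist_density": self.hist_density.tolist(),
            "reference_density": self.reference_density.tolist(),
        }


@dataclass
class OrientationSummary:
    """Axial orientation statistics of one region's plaque population."""

    n: int
    mean_axis: tuple[float, float, float]
    deviation_p50_deg: float
    deviation_p90_deg: float
    plane_deviations_deg: dict[str, dict[str, float]]
    hist_azimuth_edges: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    hist_elevation_edges: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    hist_counts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_axis": list(self.mean_axis),
            "deviation_p50_deg": self.deviation_p50_deg,
            "deviation_p90_deg": self.deviation_p90_deg,
            "plane_deviations_deg": self.plane_deviations_deg,
        }


def summarize(values: Sequence[float]) -> StatsSummary:
    """Mean, sample std, adjusted skewness and quantiles of a sample."""
    x = np.asarray(list(values), dtype=np.float64)
    if x.size == 0:
        raise DomainError("cannot summarize an empty sample")
    mean = float(x.mean())
    std = float(x.std(ddof=1)) if x.size > 1 else 0.0
    flag = std == 0.0
    skew = 0.0 if flag else float(sps.skew(x, bias=False))
    quant = {q: float(np.quantile(x, q)) for q in DEFAULT_QUANTILES}
    return StatsSummary(
        n=int(x.size), mean=mean, std=std, skewness=skew,
        quantiles=quant, skewness_flag=flag,
    )


def select_elongated(
    records: Sequence[MorphRecord], summary: StatsSummary
) -> list[MorphRecord]:
    """Keep records with sphericity strictly below ``mean + std``.

    Objects too close to a sphere have no well-defined main axis and are
    excluded from orientation analysis.  Input order is preserved.
    """
    cutoff = summary.mean + summary.std
    return [r for r in records if r.sphericity < cutoff]


def lognormal_check(volumes_um3: Sequence[float], bins: int = 30) -> LogNormalCheck:
    """Compare log-volumes against the Gaussian with matched moments."""
    v = np.asarray(list(volumes_um3), dtype=np.float64)
    if v.size < 10:
        raise DomainError(f"need >= 10 volumes, got {v.size}")
    if np.any(v <= 0):
        raise DomainError("volumes must be positive for a log-normal check")
    logs = np.log(v)
    mu = float(logs.mean())
    sd = float(logs.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise DomainError("all volumes equal: log-std is 0, check degenerate")
    ks = float(sps.kstest(logs, "norm", args=(mu, sd)).statistic)
    density, edges = np.histogram(logs, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ref = sps.norm.pdf(centers, loc=mu, scale=sd)
    return LogNormalCheck(
        n=int(v.size), log_mean=mu, log_std=sd, ks_statistic=ks,
        hist_bin_edges=edges, hist_density=density, reference_density=ref,
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two scalar samples.

    Returns ``(U, p)`` with ``U`` the statistic of the first group.  Both
    groups need n >= 3.  When both n <= 8 the p-value is computed by exact
    enumeration of all label arrangements using midranks (tie-corrected);
    otherwise the tie-corrected normal approximation is used.
    """
    xa = np.asarray(list(a), dtype=np.float64)
    xb = np.asarray(list(b), dtype=np.float64)
    if xa.size < 3 or xb.size < 3:
        raise DomainError("each group needs n >= 3")
    n_a, n_b = xa.size, xb.size
    pooled = np.concatenate([xa, xb])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n_a], n_a)
    if n_a <= 8 and n_b <= 8:
        mu = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mu)
        total = 0
        extreme = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(idx)], n_a)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Orientation statistics
# ---------------------------------------------------------------------------

#: Coordinate planes, named by their unit normal in the anatomical frame
#: (axis 0 dorso-ventral, axis 1 medio-lateral, axis 2 anterior-posterior).
PLANE_NORMALS = {
    "transverse": np.array([1.0, 0.0, 0.0]),  # normal to dorso-ventral
    "sagittal": np.array([0.0, 1.0, 0.0]),    # normal to medio-lateral
    "coronal": np.array([0.0, 0.0, 1.0]),     # normal to anterior-posterior
}
DEFAULT_PLANES = ("transverse", "coronal")


def orientation_tensor(axes: np.ndarray) -> np.ndarray:
    """Mean outer product ``(1/n) sum a_i a_i^T`` of unit axes (n, 3)."""
    axes = np.asarray(axes, dtype=np.float64)
    return axes.T @ axes / axes.shape[0]


def mean_axis_of(axes: np.ndarray) -> np.ndarray:
    """Undirected mean axis: principal eigenvector of the orientation tensor."""
    t = orientation_tensor(axes)
    evals, evecs = np.linalg.eigh(t)
    return canonicalize_axis(evecs[:, int(np.argmax(evals))])


def _plane_deviation(axes: np.ndarray, mean: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """In-plane angular deviations after projecting axes into a plane."""
    proj = axes - np.outer(axes @ normal, normal)
    norms = np.linalg.norm(proj, axis=1)
    ok = norms > 1e-12
    m = mean - (mean @ normal) * normal
    mn = np.linalg.norm(m)
    if mn < 1e-12 or not ok.any():
        return np.array([])
    m = m / mn
    cosang = np.abs(proj[ok] @ m) / norms[ok]
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def orientation_summary(
    records: Sequence[MorphRecord],
    group_by_region: bool = True,
    planes: Sequence[str] = DEFAULT_PLANES,
    hist_bin_deg: float = ORIENT_HIST_BIN_DEG,
) -> dict[str, OrientationSummary]:
    """Per-region axial orientation statistics.

    Records with a tie-flagged (undefined) axis are ignored; empty groups
    are skipped.  Deviations are ``arccos |a_i . mean|`` so axis sign never
    matters; the azimuth-elevation histogram counts both antipodal
    representations of each axis, reproducing the paired clusters such data
    show at (azimuth, elevation) and (azimuth +- 180, -elevation).
    """
    groups: dict[str, list[MorphRecord]] = {}
    for r in records:
        if r.axis_tie_flag or r.principal_axis is None:
            continue
        key = r.region if group_by_region else "all"
        groups.setdefault(key, []).append(r)
    out: dict[str, OrientationSummary] = {}
    for region, recs in groups.items():
        axes = np.array([r.principal_axis for r in recs], dtype=np.float64)
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        mean = mean_axis_of(axes)
        dev = np.degrees(np.arccos(np.clip(np.abs(axes @ mean), -1.0, 1.0)))
        plane_dev: dict[str, dict[str, float]] = {}
        for name in planes:
            d = _plane_deviation(axes, mean, PLANE_NORMALS[name])
            if d.size:
                plane_dev[name] = {
                    "p50": float(np.percentile(d, 50)),
                    "p90": float(np.percentile(d, 90)),
                }
        az_edges = np.arange(-180.0, 180.0 + hist_bin_deg, hist_bin_deg)
        el_edges = np.arange(-90.0, 90.0 + hist_bin_deg, hist_bin_deg)
        az_list, el_list = [], []
        for ax in np.concatenate([axes, -axes]):  # both antipodal reps
            az, el = axis_to_angles(ax)
            az_list.append(az)
            el_list.append(el)
        hist, _, _ = np.histogram2d(az_list, el_list, bins=[az_edges, el_edges])
        out[region] = OrientationSummary(
            n=len(recs),
            mean_axis=tuple(mean),  # type: ignore[arg-type]
            deviation_p50_deg=float(np.percentile(dev, 50)),
            deviation_p90_deg=float(np.percentile(dev, 90)),
            plane_deviations_deg=plane_dev,
            hist_azimuth_edges=az_edges,
            hist_elevation_edges=el_edges,
            hist_counts=hist,
        )
    return out
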