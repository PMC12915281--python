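"""Cross-modality coregistration and regional statistics.

The FRET camera and the high-speed mapping cameras view the same heart at
different pixel pitches; fiducial point pairs fit a least-squares similarity
transform (scale, rotation, translation) between the grids, ROIs drawn on
one grid are rasterised onto the other, and regional summaries (mean ± SEM
over hearts) and paired two-tailed t-tests reproduce the study's statistics.

Coordinates are 0-based row-major ``(row, col)`` throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import MultiPoint
from skimage import transform as sktransform

from .errors import AnalysisError, ConfigurationError


@dataclass
class SimilarityTransform:
    """Similarity map ``dst = scale * R(rotation) @ src + translation``.

    ``translation`` is (dy, dx) pixels and ``rmse`` the fiducial residual.
    """

    scale: float
    rotation: float
    translation: tuple
    rmse: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (row, col, 1) columns."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        # Rotation in (row, col) coordinates matching the (x, y) convention
        # rotated into image axes.
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.translation[0]],
                [self.scale * s, self.scale * c, self.translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array of (row, col) points."""
        pts = np.asarray(points, dtype=float)
        ones = np.ones((len(pts), 1))
        out = (self.matrix @ np.hstack([pts, ones]).T).T
        return out[:, :2]

    def inverse(self) -> "SimilarityTransform":
        """Analytic inverse transform."""
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        ty, tx = self.translation
        dy = -inv_scale * (c * ty - s * tx)
        dx = -inv_scale * (s * ty + c * tx)
        return SimilarityTransform(inv_scale, inv_rot, (dy, dx), self.rmse)


@dataclass
class RegionalSummary:
    """Per-region summary over hearts: mean ± SEM with N = number of hearts."""

    region: str
    per_heart_values: list = field(default_factory=list)
    mean: float = 0.0
    sem: float | None = None
    n_hearts: int = 0


def fit_alignment(src_points, dst_points) -> SimilarityTransform:
    """Least-squares similarity transform from fiducial point pairs.

    Requires at least 2 non-coincident pairs; the returned transform maps
    source (row, col) fiducials onto their targets with the reported RMSE.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ConfigurationError("src and dst must be matching (N, 2) arrays")
    if len(src) < 2:
        raise ConfigurationError("at least 2 fiducial pairs are required")
    if np.allclose(src, src[0]):
        raise ConfigurationError("degenerate configuration: coincident source points")

    # skimage works in (x, y) = (col, row); flip, estimate, flip back.
    if hasattr(sktransform.SimilarityTransform, "from_estimate"):
        tf = sktransform.SimilarityTransform.from_estimate(src[:, ::-1], dst[:, ::-1])
        ok = bool(tf)
    else:  # older scikit-image
        tf = sktransform.SimilarityTransform()
        ok = tf.estimate(src[:, ::-1], dst[:, ::-1])
    if not ok or not np.isfinite(tf.scale) or tf.scale <= 0:
        raise ConfigurationError("degenerate fiducial configuration")
    ty, tx = tf.translation[1], tf.translation[0]
    out = SimilarityTransform(
        scale=float(tf.scale),
        rotation=float(-tf.rotation),
        translation=(float(ty), float(tx)),
    )
    residual = out.apply(src) - dst
    out.rmse = float(np.sqrt((residual**2).sum(axis=1).mean()))
    return out


def map_roi(
    roi_pixels, transform: SimilarityTransform, target_shape: tuple
) -> np.ndarray:
    """Rasterise an ROI from the source grid onto the target grid.

    ``roi_pixels`` is a boolean grid or an (N, 2) array of (row, col)
    pixels. Each source pixel contributes its four corners; a target pixel
    is included when its centre falls inside the convex hull of the
    transformed corners.

    Raises
    ------
    AnalysisError
        If the mapped ROI lies fully outside the target grid.
    """
    roi = np.asarray(roi_pixels)
    if roi.ndim == 2 and roi.dtype == bool:
        pts = np.argwhere(roi).astype(float)
    else:
        pts = np.asarray(roi, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise AnalysisError("empty ROI")
    corners = np.concatenate(
        [pts + np.array(d) for d in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    mapped = transform.apply(corners)
    hull = MultiPoint([tuple(p[::-1]) for p in mapped]).convex_hull  # (x=col, y=row)

    rmin = max(0, int(np.floor(mapped[:, 0].min())))
    rmax = min(target_shape[0] - 1, int(np.ceil(mapped[:, 0].max())))
    cmin = max(0, int(np.floor(mapped[:, 1].min())))
    cmax = min(target_shape[1] - 1, int(np.ceil(mapped[:, 1].max())))
    out = np.zeros(target_shape, dtype=bool)
    if rmin > rmax or cmin > cmax:
        raise AnalysisError("ROI maps fully outside the target grid")
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    inside = shapely.contains_xy(hull, cc.ravel().astype(float), rr.ravel().astype(float))
    out[rr.ravel()[inside], cc.ravel()[inside]] = True
    if not out.any():
        raise AnalysisError("ROI maps fully outside the target grid")
    return out


def paired_t(values_a, values_b):
    """Classical paired two-tailed t-test over hearts.

    Returns ``(t, df, p, mean_diff)`` with ``df = n - 1``. Identical samples
    give t = 0, p = 1; zero-variance nonzero differences report p = 0 with a
    warning rather than failing.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ConfigurationError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ConfigurationError("paired t-test requires n >= 2")
    d = a - b
    mean_diff = float(d.mean())
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, n - 1, 1.0, 0.0
        warnings.warn(
            "zero-variance nonzero differences: p reported as the limit 0",
            stacklevel=2,
        )
        return float(np.sign(d[0]) * np.inf), n - 1, 0.0, mean_diff
    res = stats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue), mean_diff


def summarize(per_heart_values, region: str) -> RegionalSummary:
    """Mean ± SEM (sample SD / sqrt(N)) over hearts; SEM undefined at N = 1."""
    values = [float(v) for v in np.asarray(per_heart_values, dtype=float).ravel()]
    if len(values) == 0:
        raise AnalysisError("no values to summarize")
    n = len(values)
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else None
    return RegionalSummary(
        region=region,
        per_heart_values=values,
        mean=float(np.mean(values)),
        sem=sem,
        n_hearts=n,
    )
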