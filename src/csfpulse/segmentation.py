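"""CSF segmentation under partial volume via spatially regularized fuzzy c-means.

CSF voxels are distinguished from static tissue by their temporal velocity
fluctuation: the feature image is the per-voxel temporal standard deviation
of velocity.  Partial-volume mixing at ~2 mm voxels makes hard thresholding
unreliable, so a fuzzy (soft) clustering is used: standard fuzzy c-means on
the feature values, with each membership iteratively multiplied by the mean
membership in a local window (raised to a weight) and renormalized — a
common spatial-FCM regularization that pulls isolated noisy voxels toward
their neighborhood's class.

Hard ROI masks are cut from the membership map inside a user-supplied rough
rectangle (the analyst outlines the aqueduct / foramen magnum approximately;
the clustering does the fine work), keeping the largest connected component.
Segmentation can be bypassed entirely by loading mask files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.ndimage import uniform_filter

from .core import ROIMask, VelocitySeries

__all__ = [
    "MembershipMap",
    "feature_image",
    "spatial_fuzzy_cluster",
    "mask_from_membership",
    "segment_regions",
    "dice",
]


@dataclass
class MembershipMap:
    """Fuzzy memberships, shape (k, H, W); sums to 1 over clusters everywhere."""

    memberships: np.ndarray
    centers: np.ndarray  # cluster centers in feature units, ascending order not guaranteed
    n_iter: int
    converged: bool
    objective_history: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.memberships.shape[0]

    @property
    def csf_cluster(self) -> int:
        """Index of the high-fluctuation (CSF) cluster."""
        return int(np.argmax(self.centers))


def feature_image(vel: VelocitySeries) -> np.ndarray:
    """Per-voxel temporal SD of velocity (cm/s): moving fluid lights up."""
    data = vel.data
    if data.shape[-1] < 2:
        raise ValueError("feature image needs at least 2 frames")
    feat = data.std(axis=-1, ddof=0)
    if feat.ndim == 3 and feat.shape[2] == 1:
        feat = feat[:, :, 0]
    return feat


def spatial_fuzzy_cluster(
    feature: np.ndarray,
    k: int = 2,
    m: float = 2.0,
    spatial_weight: float = 1.0,
    window: int = 3,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int = 0,
) -> MembershipMap:
    """Cluster a 2D feature map into k fuzzy classes with spatial smoothing.

    Alternates the two plain fuzzy-c-means half-steps (centers from
    membership-weighted means; memberships from inverse-distance ratios with
    fuzzifier ``m``) with a spatial step that multiplies each membership map
    by its ``window x window`` local mean raised to ``spatial_weight`` and
    renormalizes.  With ``spatial_weight=0`` this reduces exactly to plain
    FCM, whose objective the iteration never increases.

    Initialization is a deterministic quantile split of the feature values
    (the seed only breaks exact center ties), so identical inputs give
    identical memberships.

    Parameters
    ----------
    feature : 2D array
        Feature image (here: temporal velocity SD, cm/s).
    k : int
        Number of clusters (>= 2); 2 = CSF vs background.
    m : float
        Fuzzifier (> 1); 2 is the field-standard default.
    spatial_weight : float
        Exponent on the local mean membership; 0 disables the spatial step.
    window : int
        Side of the (odd) spatial averaging window, voxels.
    """
    feature = np.asarray(feature, dtype=float)
    if feature.ndim == 3 and feature.shape[2] == 1:
        feature = feature[:, :, 0]
    if feature.ndim != 2:
        raise ValueError(f"feature map must be 2D, got shape {feature.shape}")
    if not np.all(np.isfinite(feature)):
        raise ValueError("feature map contains non-finite values")
    if k < 2:
        raise ValueError("need k >= 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if np.ptp(feature) == 0:
        raise ValueError("degenerate input: feature image is constant")

    shape = feature.shape
    f = feature.ravel()
    rng = np.random.default_rng(seed)

    # init: centers at interior quantiles of the feature distribution
    centers = np.quantile(f, [(i + 1) / (k + 1) for i in range(k)])
    while np.any(np.diff(np.sort(centers)) == 0):  # exact ties: nudge apart
        centers = centers + rng.normal(0, 1e-9 * max(np.ptp(f), 1.0), size=k)

    expo = 1.0 / (m - 1.0)
    eps = 1e-12
    u = _fcm_memberships(f, centers, expo, eps)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u_prev = u
        um = u**m
        centers = (um @ f) / np.maximum(um.sum(axis=1), eps)
        u = _fcm_memberships(f, centers, expo, eps)
        # objective of the plain-FCM half-steps (monotone when
        # spatial_weight == 0)
        d2 = (f[np.newaxis, :] - centers[:, np.newaxis]) ** 2
        history.append(float(np.sum((u**m) * d2)))
        if spatial_weight > 0:
            maps = u.reshape(k, *shape)
            local = uniform_filter(maps, size=(1, window, window), mode="nearest")
            u = (maps * np.clip(local, eps, None) ** spatial_weight).reshape(k, -1)
            u = u / np.maximum(u.sum(axis=0, keepdims=True), eps)
        if np.max(np.abs(u - u_prev)) < tol:
            converged = True
            break

    return MembershipMap(
        memberships=u.reshape(k, *shape),
        centers=centers,
        n_iter=it,
        converged=converged,
        objective_history=history,
    )


def _fcm_memberships(f: np.ndarray, centers: np.ndarray, expo: float, eps: float) -> np.ndarray:
    d2 = (f[np.newaxis, :] - centers[:, np.newaxis]) ** 2
    d2 = np.maximum(d2, eps)
    inv = d2 ** (-expo)
    return inv / inv.sum(axis=0, keepdims=True)


def mask_from_membership(
    membership: MembershipMap,
    rect: tuple[int, int, int, int],
    threshold: float = 0.5,
    label: str = "aqueduct",
) -> ROIMask:
    """Cut a hard ROI mask from the CSF-cluster membership inside a rectangle.

    ``rect`` is ``(x0, y0, x1, y1)``, 0-based, half-open, in array index
    order (axis 0, axis 1).  Voxels inside the rectangle with CSF membership
    above ``threshold`` are kept; of those, only the largest 8-connected
    component survives (ties broken by lowest component label, i.e. scan
    order).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    csf = membership.memberships[membership.csf_cluster]
    h, w = csf.shape
    x0, y0, x1, y1 = rect
    x0c, y0c = max(0, x0), max(0, y0)
    x1c, y1c = min(h, x1), min(w, y1)
    if x0c >= x1c or y0c >= y1c:
        raise ValueError(f"rectangle {rect} does not overlap the {h}x{w} image")
    window = np.zeros_like(csf, dtype=bool)
    window[x0c:x1c, y0c:y1c] = True
    cand = window & (csf > threshold)
    if not cand.any():
        raise ValueError(
            f"no voxels above membership threshold {threshold} inside rectangle "
            f"{rect}; lower the threshold or move/enlarge the rectangle"
        )
    comp, n_comp = cc_label(cand, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        sizes = np.bincount(comp.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        cand = comp == keep
    return ROIMask(mask=cand, label=label)


def segment_regions(
    vel: VelocitySeries,
    rects: dict[str, tuple[int, int, int, int]],
    threshold: float = 0.5,
    **cluster_kwargs,
) -> dict[str, ROIMask]:
    """End-to-end segmentation: feature -> per-rectangle fuzzy clustering -> masks.

    Clustering runs separately inside each rough rectangle (k=2, CSF vs
    background): CSF occupies a tiny minority of the full slice, and region
    feature levels differ by an order of magnitude between the aqueduct and
    the foramen magnum, so a single global clustering would absorb the
    fainter region into background.  The rectangle is the analyst's rough
    outline; within it the two classes are separable.
    """
    feat = feature_image(vel)
    h, w = feat.shape
    out: dict[str, ROIMask] = {}
    for name, (x0, y0, x1, y1) in rects.items():
        x0c, y0c, x1c, y1c = max(0, x0), max(0, y0), min(h, x1), min(w, y1)
        if x0c >= x1c or y0c >= y1c:
            raise ValueError(f"rectangle {(x0, y0, x1, y1)} for {name!r} misses the image")
        crop = feat[x0c:x1c, y0c:y1c]
        mm = spatial_fuzzy_cluster(crop, **cluster_kwargs)
        local = mask_from_membership(
            mm, (0, 0, crop.shape[0], crop.shape[1]), threshold=threshold, label=name
        )
        full = np.zeros((h, w), dtype=bool)
        full[x0c:x1c, y0c:y1c] = local.mask
        out[name] = ROIMask(mask=full, label=name)
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
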