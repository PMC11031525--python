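"""Normal-vs-AAOCA classification from a segmented label volume.

The decision is two-staged.  First a connectivity rule: a correctly segmented
normal coronary tree has exactly two 3D connected components (left and right
trunks); a shared ostium produces one component and separate origins of the
left anterior descending and circumflex produce three, so any count other
than two is called anomalous outright.  Second, for two-component cases, the
origin angle: each trunk's ostium is the coronary voxel closest to the aorta;
both ostia are projected onto the axial plane halfway between their Z values;
the angle alpha at the aortic centroid of that plane between the two
centroid-to-ostium directions separates normal (wide) from anomalous (narrow)
origins via a decision stump.  The reference threshold fitted on clinical
data is 73 degrees; anomalous origin angles cluster around 30 degrees
(quartiles 20-46), normal ones around 135 (quartiles 121-154).

An optional minimum-size filter drops spurious small components (e.g. a
disconnected blob of mislabelled voxels near the root) before counting.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    AllComponentsRemovedError,
    ComponentCountError,
    DegenerateAngleError,
    EmptyAortaError,
    EmptyCoronaryMaskError,
    StumpFitError,
)
from .metrics import ANOMALOUS, NORMAL
from .volume_io import LabelVolume

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class CoronaryComponents:
    """Connected components of the coronary (label 2) mask."""

    count: int
    components: list[np.ndarray]  # each an (n_i, 3) int array of voxel indices
    volumes_ml: list[float]
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for comp in self.components:
            m[comp[:, 0], comp[:, 1], comp[:, 2]] = True
        return m


@dataclass
class OstiumPoint:
    """Voxel coordinates (i, j, k) of a coronary origin."""

    i: int
    j: int
    k: int

    def as_array(self) -> np.ndarray:
        return np.array([self.i, self.j, self.k], dtype=float)


@dataclass
class OriginAngleResult:
    ostium_a: OstiumPoint
    ostium_b: OstiumPoint
    z_half: float
    centroid: tuple[float, float]
    alpha_deg: float


@dataclass
class StumpModel:
    """Depth-1 decision tree on the origin angle: alpha < threshold => anomalous."""

    threshold_deg: float = 73.0
    training_accuracy: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.threshold_deg < 180.0:
            raise ValueError(f"threshold must lie in (0, 180), got {self.threshold_deg}")

    def predict(self, alpha_deg: float) -> str:
        # Strict inequality: boundary equality counts as normal.
        return ANOMALOUS if alpha_deg < self.threshold_deg else NORMAL


@dataclass
class ClassificationResult:
    label: str
    reason: str  # "connectivity" or "angle"
    n_components: int
    alpha_deg: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "reason": self.reason,
            "n_components": self.n_components,
            "alpha_deg": self.alpha_deg,
            "warnings": list(self.warnings),
        }


def coronary_components(lv: LabelVolume, connectivity: int = 26) -> CoronaryComponents:
    """3D connected components of the coronary mask under 6/18/26-connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = lv.data == 2
    if not mask.any():
        raise EmptyCoronaryMaskError("no coronary voxels (label 2) in the volume")
    labelled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    voxel_ml = float(np.prod(lv.spacing)) / 1000.0  # mm^3 -> ml
    components, volumes = [], []
    for lab in range(1, n + 1):
        idx = np.argwhere(labelled == lab)
        components.append(idx)
        volumes.append(idx.shape[0] * voxel_ml)
    return CoronaryComponents(
        count=n,
        components=components,
        volumes_ml=volumes,
        shape=lv.shape,
        spacing=lv.spacing,
    )


def filter_small_components(
    cc: CoronaryComponents, min_volume_ml: float = 0.0
) -> tuple[CoronaryComponents, list[str]]:
    """Drop components smaller than ``min_volume_ml``; 0 disables the filter."""
    if min_volume_ml < 0:
        raise ValueError("min_volume_ml must be >= 0")
    if min_volume_ml == 0:
        return cc, []
    keep = [i for i, v in enumerate(cc.volumes_ml) if v >= min_volume_ml]
    removed = [i for i in range(cc.count) if i not in keep]
    if not keep:
        raise AllComponentsRemovedError(
            f"minimum-size filter ({min_volume_ml} ml) removed all {cc.count} components"
        )
    notes = [
        f"removed component {i} ({cc.volumes_ml[i]:.3f} ml < {min_volume_ml} ml)"
        for i in removed
    ]
    return (
        CoronaryComponents(
            count=len(keep),
            components=[cc.components[i] for i in keep],
            volumes_ml=[cc.volumes_ml[i] for i in keep],
            shape=cc.shape,
            spacing=cc.spacing,
        ),
        notes,
    )


def detect_ostia(lv: LabelVolume, cc: CoronaryComponents) -> tuple[OstiumPoint, OstiumPoint]:
    """Per trunk, the coronary voxel nearest (Euclidean, mm) to any aorta voxel.

    Ties go to the smallest linear (ravel-order) index, which np.argmin
    guarantees.
    """
    if cc.count != 2:
        raise ComponentCountError(f"ostium detection needs exactly 2 components, got {cc.count}")
    aorta = lv.data == 1
    if not aorta.any():
        raise EmptyAortaError("no aortic-root voxels (label 1) in the volume")
    dist = ndimage.distance_transform_edt(~aorta, sampling=lv.spacing)
    ostia = []
    for comp in cc.components:
        # np.argwhere emits indices in ravel (C) order, so argmin's
        # first-occurrence rule realises the smallest-linear-index tie-break.
        d = dist[comp[:, 0], comp[:, 1], comp[:, 2]]
        best = comp[int(np.argmin(d))]
        ostia.append(OstiumPoint(int(best[0]), int(best[1]), int(best[2])))
    return ostia[0], ostia[1]


def _nearest_slice(z_half: float, nz: int) -> int:
    # Nearest integer slice; exact .5 ties resolve toward the lower index.
    k = int(np.ceil(z_half - 0.5))
    return min(max(k, 0), nz - 1)


def origin_angle(lv: LabelVolume, a: OstiumPoint, b: OstiumPoint) -> OriginAngleResult:
    """Origin angle alpha between centroid->ostium directions in the halfway plane.

    z_half is the mean of the two ostium Z indices; both ostia are projected
    onto that axial plane by dropping Z; the aortic centroid is the mean
    (i, j) of label-1 voxels on the nearest integer slice (falling back to the
    two adjacent slices if that one holds no aorta).
    """
    z_half = (a.k + b.k) / 2.0
    nz = lv.shape[2]
    k0 = _nearest_slice(z_half, nz)
    centroid = None
    for k in (k0, k0 - 1, k0 + 1):
        if 0 <= k < nz:
            ij = np.argwhere(lv.data[:, :, k] == 1)
            if ij.size:
                centroid = ij.mean(axis=0)
                break
    if centroid is None:
        raise EmptyAortaError(
            f"no aortic-root voxels on the halfway slice {k0} or its neighbours"
        )
    va = np.array([a.i, a.j], dtype=float) - centroid
    vb = np.array([b.i, b.j], dtype=float) - centroid
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise DegenerateAngleError("an ostium projects onto the aortic centroid")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    alpha = float(np.degrees(np.arccos(cosang)))
    return OriginAngleResult(
        ostium_a=a,
        ostium_b=b,
        z_half=z_half,
        centroid=(float(centroid[0]), float(centroid[1])),
        alpha_deg=alpha,
    )


def fit_decision_stump(angles, labels) -> StumpModel:
    """Fit the single angle threshold maximising training accuracy.

    Candidate thresholds are midpoints between consecutive sorted angles; the
    rule is alpha < threshold => anomalous.  Among equally accurate splits the
    midpoint of the widest separating gap wins.  If the classes interleave so
    that no split is perfect, the best achievable split is returned with a
    warning recorded on the model.
    """
    angles = np.asarray(list(angles), dtype=float)
    labels = list(labels)
    if len(angles) != len(labels):
        raise ValueError("angles and labels must have equal length")
    for lab in labels:
        if lab not in (NORMAL, ANOMALOUS):
            raise ValueError(f"unknown label {lab!r}")
    y = np.array([lab == ANOMALOUS for lab in labels])
    if y.all() or not y.any():
        raise StumpFitError("both classes must be present to fit the stump")
    order = np.argsort(angles, kind="stable")
    a_sorted = angles[order]
    uniq = np.unique(a_sorted)
    if uniq.size < 2:
        raise StumpFitError("all angles identical; no split exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    gaps = uniq[1:] - uniq[:-1]
    best_t, best_acc, best_gap = None, -1.0, -1.0
    for t, g in zip(mids, gaps):
        acc = float(((angles < t) == y).mean())
        if acc > best_acc or (acc == best_acc and g > best_gap):
            best_t, best_acc, best_gap = float(t), acc, float(g)
    notes = []
    if best_acc < 1.0:
        notes.append(
            f"classes are not separable by a single threshold; best training accuracy {best_acc:.3f}"
        )
        _warnings.warn(notes[-1], stacklevel=2)
    return StumpModel(threshold_deg=best_t, training_accuracy=best_acc, warnings=notes)


def classify_geometry(
    lv: LabelVolume,
    stump: StumpModel | None = None,
    min_volume_ml: float = 0.0,
    connectivity: int = 26,
) -> ClassificationResult:
    """Full two-stage decision: connectivity rule, then origin angle.

    Component counts other than two are anomalous by connectivity (counts of
    four or more additionally carry a warning, as the clinical taxonomy only
    anticipates one, two or three).  Exactly two components proceed to ostium
    detection and the angle stump.
    """
    stump = stump or StumpModel()
    cc = coronary_components(lv, connectivity=connectivity)
    cc, notes = filter_small_components(cc, min_volume_ml)
    if cc.count != 2:
        if cc.count not in (1, 3):
            notes.append(
                f"component count {cc.count} outside the anticipated taxonomy {{1, 2, 3}}"
            )
        return ClassificationResult(
            label=ANOMALOUS,
            reason="connectivity",
            n_components=cc.count,
            warnings=notes,
        )
    a, b = detect_ostia(lv, cc)
    res = origin_angle(lv, a, b)
    return ClassificationResult(
        label=stump.predict(res.alpha_deg),
        reason="angle",
        n_components=2,
        alpha_deg=res.alpha_deg,
        warnings=notes,
    )
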