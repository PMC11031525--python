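"""Synthetic CTA-like vascular phantoms with paired ground-truth labels.

Each phantom contains a bright vertical cylinder (the aortic root, label 1)
and one to three thinner curved tubes (coronary arteries, label 2) that start
on the aortic surface at controlled azimuths and heights, then curve outward
and inferiorly along quadratic Bezier paths rasterised as swept spheres.

Variants mirror the anatomical taxonomy used by the classifier:

``normal``
    two trunks with ostium azimuthal separation drawn from [121, 154] degrees
    (the observed quartile range of normal origin angles);
``anomalous_close``
    two trunks with separation drawn from [20, 46] degrees (the anomalous
    quartile range) — still two connected components, caught by the origin
    angle;
``anomalous_shared``
    both trunks leave a single shared ostium, giving one connected component;
``anomalous_three``
    three separate trunks, giving three connected components;
``retroaortic``
    a two-trunk variant whose second tube wraps behind the aorta; included
    for completeness, outside the scope of the recovery experiments.

Intensities are class-conditional Gaussians on the Hounsfield scale
(contrast lumen ~ N(350, 20), soft tissue ~ N(-50, 20) by default), with a
small Gaussian blur applied to the noiseless field first to mimic partial
volume averaging.  Everything is reproducible from ``noise_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PhantomGeometryError
from .metrics import ANOMALOUS, NORMAL
from .volume_io import IntensityVolume, LabelVolume, write_labels, write_volume

VARIANTS = (
    "normal",
    "anomalous_close",
    "anomalous_shared",
    "anomalous_three",
    "retroaortic",
)

# Azimuthal ostium separation ranges (degrees) per variant, from the observed
# quartiles of the origin angle in normal vs anomalous anatomies.
NORMAL_SEPARATION_RANGE = (121.0, 154.0)
CLOSE_SEPARATION_RANGE = (20.0, 46.0)

EXPECTED_COMPONENTS = {
    "normal": 2,
    "anomalous_close": 2,
    "anomalous_shared": 1,
    "anomalous_three": 3,
    "retroaortic": 2,
}


@dataclass
class PhantomSpec:
    """Generative parameters of one phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    variant: str = "normal"
    aorta_radius_vox: float = 10.0
    coronary_radius_vox: float = 2.0
    ostium_azimuths_deg: list[float] | None = None
    ostium_z: list[float] | None = None
    lumen_hu_mean: float = 350.0
    lumen_hu_sd: float = 20.0
    tissue_hu_mean: float = -50.0
    tissue_hu_sd: float = 20.0
    blur_sigma: float = 0.5
    noise_seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.coronary_radius_vox < 1 or self.aorta_radius_vox <= self.coronary_radius_vox:
            raise ValueError("radii must satisfy aorta_radius > coronary_radius >= 1")
        self.shape = tuple(int(n) for n in self.shape)


@dataclass
class PhantomTruth:
    """Ground truth paired with a generated phantom."""

    spec: PhantomSpec
    true_ostia: list[tuple[float, float, float]]
    true_separation_deg: float | None
    true_label: str
    expected_n_components: int


def _unit(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    return np.array([np.cos(th), np.sin(th)])


def _bezier(p0, p1, p2, n_steps: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_steps)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _rasterize_tube(mask: np.ndarray, path: np.ndarray, radius: float) -> None:
    """Mark all voxels within ``radius`` of the polyline sample points."""
    shape = mask.shape
    r_int = int(np.ceil(radius))
    # sphere stencil offsets
    off = np.arange(-r_int, r_int + 1)
    oi, oj, ok = np.meshgrid(off, off, off, indexing="ij")
    stencil = np.stack([oi, oj, ok], axis=-1).reshape(-1, 3)
    for p in path:
        centre = np.round(p).astype(int)
        pts = centre + stencil
        d2 = np.sum((pts - p) ** 2, axis=1)
        pts = pts[d2 <= radius**2]
        if (pts < 0).any() or (pts >= np.array(shape)).any():
            raise PhantomGeometryError(
                f"coronary tube leaves the grid at {p} (shape {shape})"
            )
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def _tube_path(centre_xy, R, theta_deg, z0, curl_deg, reach, drop, start_radius, n_steps=90):
    """Quadratic Bezier from the aortic surface, curving outward/inferiorly.

    The path starts at ``start_radius`` from the axis — just far enough out
    that the first swept sphere is tangent to the aortic wall, so the tube
    touches the wall in a compact patch around the true ostium instead of a
    broad smear (which would blur ostium localisation).
    """
    u0 = _unit(theta_deg)
    u2 = _unit(theta_deg + curl_deg)
    p0 = np.array([*(centre_xy + start_radius * u0), z0])
    p1 = np.array([*(centre_xy + (R + 0.6 * reach) * u0), z0 - 0.25 * drop])
    p2 = np.array([*(centre_xy + (R + reach) * u2), z0 - drop])
    return _bezier(p0, p1, p2, n_steps)


def _resolve_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Sample or validate ostium azimuths and heights for the variant."""
    nz = spec.shape[2]
    base = float(rng.uniform(0.0, 360.0))
    variant = spec.variant

    if spec.ostium_azimuths_deg is not None:
        azimuths = [float(a) for a in spec.ostium_azimuths_deg]
    elif variant in ("normal", "retroaortic"):
        sep = float(rng.uniform(*NORMAL_SEPARATION_RANGE))
        azimuths = [base, base + sep]
    elif variant == "anomalous_close":
        sep = float(rng.uniform(*CLOSE_SEPARATION_RANGE))
        azimuths = [base, base + sep]
    elif variant == "anomalous_shared":
        azimuths = [base, base]
    else:  # anomalous_three
        azimuths = [base, base + rng.uniform(85.0, 125.0), base + rng.uniform(195.0, 250.0)]

    if spec.ostium_z is not None:
        z_ost = [float(z) for z in spec.ostium_z]
    else:
        z_top = float(rng.uniform(0.58 * nz, 0.66 * nz))
        # Offsets between trunks keep the halfway-plane projection non-trivial
        # and, for closely spaced ostia, keep the tubes from touching.
        if variant == "anomalous_close":
            dz = float(rng.uniform(5.0, 6.0))
        else:
            dz = float(rng.uniform(2.0, 6.0))
        if len(azimuths) == 3:
            z_ost = [z_top, z_top - dz, z_top - 2.0]
        elif variant == "anomalous_shared":
            z_ost = [z_top, z_top]
        else:
            z_ost = [z_top, z_top - dz]
    if len(z_ost) != len(azimuths):
        raise ValueError("ostium_z and ostium_azimuths_deg lengths differ")
    return azimuths, z_ost


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume, PhantomTruth]:
    """Generate one phantom: intensities, labels and the generative truth."""
    rng = np.random.default_rng(spec.noise_seed)
    nx, ny, nz = spec.shape
    R = spec.aorta_radius_vox
    rc = spec.coronary_radius_vox
    centre_xy = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])

    azimuths, z_ost = _resolve_geometry(spec, rng)
    spec = replace(spec, ostium_azimuths_deg=list(azimuths), ostium_z=list(z_ost))

    # Aortic root: vertical cylinder plus a small funnel-like bump at each
    # ostium.  The bump models the ostial junction; it also pins the point of
    # closest aorta-coronary approach to the true ostium, which keeps
    # nearest-voxel ostium detection well-posed on a discrete grid.
    z_lo, z_hi = 0.10 * nz, 0.90 * nz
    xi, yi, zi = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r2 = (xi - centre_xy[0]) ** 2 + (yi - centre_xy[1]) ** 2
    aorta = (r2 <= R**2) & (zi >= z_lo) & (zi <= z_hi)
    for theta, z0 in zip(azimuths, z_ost):
        u0 = _unit(theta)
        kz = int(round(z0))
        for t in np.arange(R + 0.25, R + 1.9, 0.25):
            p = np.round(centre_xy + t * u0).astype(int)
            if 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= kz < nz:
                aorta[p[0], p[1], kz] = True

    reach = 1.5 * R
    drop = 1.2 * R
    if max(centre_xy) + R + reach + rc + 0.5 >= min(nx, ny) - 1:
        raise PhantomGeometryError(
            f"tube reach {R + reach + rc:.1f} vox does not fit in shape {spec.shape}"
        )

    coronary = np.zeros(spec.shape, dtype=bool)
    ostia = []
    for t_idx, (theta, z0) in enumerate(zip(azimuths, z_ost)):
        if spec.variant == "retroaortic" and t_idx == 1:
            # Wrap behind the aorta: wide tangential control point keeps the
            # tube centerline outside the aortic cylinder the whole way.
            p0 = np.array([*(centre_xy + (R + rc + 2.0) * _unit(theta)), z0])
            p1 = np.array([*(centre_xy + 2.2 * R * _unit(theta + 75.0)), z0 - 0.4 * drop])
            p2 = np.array([*(centre_xy + 1.45 * R * _unit(theta + 150.0)), z0 - drop])
            path = _bezier(p0, p1, p2, 90)
        else:
            if spec.variant == "anomalous_shared":
                curl = 28.0 if t_idx == 0 else -28.0
            else:
                curl = 8.0
            path = _tube_path(
                centre_xy, R, theta, z0, curl, reach, drop, start_radius=R + rc + 2.0
            )
        _rasterize_tube(coronary, path, rc)
        # The coronary lumen proper begins where the tube clears the ostial
        # funnel, at radius R + 2 from the axis.
        u0 = _unit(theta)
        r_ost = R + 2.0
        ostia.append(
            (
                float(centre_xy[0] + r_ost * u0[0]),
                float(centre_xy[1] + r_ost * u0[1]),
                float(z0),
            )
        )
    coronary &= ~aorta  # classes are disjoint; the aorta wins at the surface

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[aorta] = 1
    labels[coronary] = 2

    # Class-conditional HU field, partial-volume blur, then additive noise.
    lumen = labels > 0
    base = np.where(lumen, spec.lumen_hu_mean, spec.tissue_hu_mean).astype(np.float64)
    if spec.blur_sigma > 0:
        base = ndimage.gaussian_filter(base, spec.blur_sigma)
    sd = np.where(lumen, spec.lumen_hu_sd, spec.tissue_hu_sd)
    intensities = base + rng.standard_normal(spec.shape) * sd

    if spec.variant == "anomalous_shared":
        separation: float | None = 0.0
    elif len(azimuths) == 2:
        separation = float(abs(azimuths[1] - azimuths[0]))
        separation = min(separation % 360.0, 360.0 - separation % 360.0)
    else:
        separation = None

    truth = PhantomTruth(
        spec=spec,
        true_ostia=ostia,
        true_separation_deg=separation,
        true_label=NORMAL if spec.variant == "normal" else ANOMALOUS,
        expected_n_components=EXPECTED_COMPONENTS[spec.variant],
    )
    vol = IntensityVolume(intensities.astype(np.float32), spec.spacing)
    lv = LabelVolume(labels, spec.spacing)
    return vol, lv, truth


def _variant_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n phantoms to variants."""
    if not mix or abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"variant mix must sum to 1, got {mix}")
    for v in mix:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r} in mix")
    raw = {v: n * f for v, f in mix.items()}
    counts = {v: int(np.floor(x)) for v, x in raw.items()}
    short = n - sum(counts.values())
    for v, _ in sorted(raw.items(), key=lambda kv: kv[1] - np.floor(kv[1]), reverse=True)[:short]:
        counts[v] += 1
    return counts


def child_seed(base_seed: int, index: int) -> int:
    """Deterministic per-phantom seed derived from the dataset seed."""
    return int((base_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1))


def generate_dataset(
    n: int,
    mix: dict[str, float],
    base_seed: int,
    shape: tuple[int, int, int] = (64, 64, 64),
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    out_dir: str | Path | None = None,
    **spec_kwargs,
) -> tuple[list, pd.DataFrame]:
    """Generate ``n`` phantoms with a manifest and train/val/test assignment.

    Returns ``(triples, manifest)`` where each triple is the output of
    :func:`generate_phantom` and the manifest records variant, seed, split and
    truth fields per phantom.  When ``out_dir`` is given the volumes are also
    written as NIfTI pairs and their paths recorded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    counts = _variant_counts(n, mix)
    variants = [v for v, c in counts.items() for _ in range(c)]

    rng = np.random.default_rng(base_seed)
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    split_of = {}
    for rank, idx in enumerate(order):
        split_of[idx] = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    triples, rows = [], []
    for i, variant in enumerate(variants):
        seed_i = child_seed(base_seed, i)
        spec = PhantomSpec(shape=shape, variant=variant, noise_seed=seed_i, **spec_kwargs)
        vol, lv, truth = generate_phantom(spec)
        triples.append((vol, lv, truth))
        img_path = lab_path = ""
        if out_dir is not None:
            img_path = str(out_dir / f"phantom_{i:03d}_img.nii.gz")
            lab_path = str(out_dir / f"phantom_{i:03d}_lab.nii.gz")
            write_volume(vol, img_path)
            write_labels(lv, lab_path)
        rows.append(
            {
                "index": i,
                "variant": variant,
                "seed": seed_i,
                "split": split_of[i],
                "true_label": truth.true_label,
                "true_separation_deg": truth.true_separation_deg,
                "expected_n_components": truth.expected_n_components,
                "img_path": img_path,
                "lab_path": lab_path,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return triples, manifest
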