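"""Schematic digital phantom: 11 labelled subcortical/brainstem ROIs.

The geometry is deliberately non-anatomical — ellipsoids on a small grid —
because the downstream analysis operates on labels and intensities, never on
anatomy.  Nine structures are bilateral (mirrored about the mid-sagittal
plane, left and right carrying distinct integer labels); the midbrain and
pons sit on the midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROI_NAMES",
    "RIGHT_LABEL_OFFSET",
    "ROIDef",
    "PhantomSpec",
    "GroundTruth",
    "default_phantom_spec",
    "generate_phantom",
]

#: The 11 regions analysed in the study; all bilateral except midbrain/pons.
ROI_NAMES = (
    "accumbens",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
    "midbrain",
    "pons",
    "SNc",
    "SNr",
)
MIDLINE_ROIS = frozenset({"midbrain", "pons"})

#: Right-hemisphere labels are the left label plus this offset.
RIGHT_LABEL_OFFSET = 50


@dataclass(frozen=True)
class ROIDef:
    """One region: ellipsoid at ``center`` with semi-axes ``radii`` (voxels).

    Bilateral regions are rasterized twice, the right copy mirrored along
    the first (x) axis with label ``label + RIGHT_LABEL_OFFSET``.
    """

    name: str
    label: int
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    bilateral: bool = True


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 48, 30)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    roi_defs: tuple[ROIDef, ...] = ()
    background_label: int = 0
    min_roi_voxels: int = 30

    def __post_init__(self) -> None:
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm entries must be positive")
        names = [r.name for r in self.roi_defs]
        if sorted(names) != sorted(ROI_NAMES):
            raise ValueError(
                f"roi_defs must cover exactly {sorted(ROI_NAMES)}, got {sorted(names)}"
            )
        for r in self.roi_defs:
            if (r.name in MIDLINE_ROIS) == r.bilateral:
                raise ValueError(
                    f"{r.name}: bilateral must be "
                    f"{r.name not in MIDLINE_ROIS} (midline ROIs are unilateral)"
                )
        labels = [r.label for r in self.roi_defs]
        all_labels = labels + [r.label + RIGHT_LABEL_OFFSET
                               for r in self.roi_defs if r.bilateral]
        if len(set(all_labels)) != len(all_labels) or min(all_labels) <= 0:
            raise ValueError("ROI labels must be unique positive integers")
        if self.background_label in all_labels:
            raise ValueError("background_label collides with an ROI label")

    def label_lookup(self) -> dict[str, list[int]]:
        """ROI name -> list of integer labels (two for bilateral ROIs)."""
        out: dict[str, list[int]] = {}
        for r in self.roi_defs:
            labs = [r.label]
            if r.bilateral:
                labs.append(r.label + RIGHT_LABEL_OFFSET)
            out[r.name] = labs
        return out

    def rasterize(self) -> np.ndarray:
        """Paint the label volume, rejecting overlapping placements."""
        nx, ny, nz = self.grid_shape
        x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
        labels = np.full(self.grid_shape, self.background_label, dtype=np.int16)
        for roi in self.roi_defs:
            placements = [(roi.label, roi.center)]
            if roi.bilateral:
                cx, cy, cz = roi.center
                placements.append(
                    (roi.label + RIGHT_LABEL_OFFSET, (nx - 1 - cx, cy, cz))
                )
            for lab, (cx, cy, cz) in placements:
                rx, ry, rz = roi.radii
                inside = (
                    ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
                ) <= 1.0
                clash = labels[inside]
                clash = clash[clash != self.background_label]
                if clash.size:
                    raise ValueError(
                        f"ROI placement overlap: label {lab} ({roi.name}) "
                        f"collides with labels {sorted(set(int(c) for c in clash))}"
                    )
                if inside.sum() < self.min_roi_voxels:
                    raise ValueError(
                        f"ROI {roi.name} (label {lab}) occupies only "
                        f"{int(inside.sum())} voxels (< {self.min_roi_voxels})"
                    )
                labels[inside] = lab
        return labels


def default_phantom_spec() -> PhantomSpec:
    """Default 48 x 48 x 30 phantom with well-separated ellipsoids."""
    b = dict(radii=(3.0, 3.0, 2.6), bilateral=True)
    rois = (
        ROIDef("accumbens", 1, (12, 8, 8), **b),
        ROIDef("amygdala", 2, (12, 8, 16), **b),
        ROIDef("caudate", 3, (12, 8, 23), **b),
        ROIDef("hippocampus", 4, (12, 16, 8), **b),
        ROIDef("pallidum", 5, (12, 16, 16), **b),
        ROIDef("putamen", 6, (12, 16, 23), **b),
        ROIDef("thalamus", 7, (12, 24, 8), **b),
        ROIDef("SNc", 8, (12, 24, 16), **b),
        ROIDef("SNr", 9, (12, 24, 23), **b),
        ROIDef("midbrain", 10, (24, 36, 10), (3.5, 3.5, 3.0), bilateral=False),
        ROIDef("pons", 11, (24, 36, 20), (3.5, 3.5, 3.0), bilateral=False),
    )
    return PhantomSpec(roi_defs=rois)


@dataclass
class GroundTruth:
    """Per-voxel ground-truth maps for one subject (NaN outside ROIs)."""

    t1rho_map: np.ndarray
    t2rho_map: np.ndarray
    traff4_map: np.ndarray
    m0_map: np.ndarray
    mss_frac_map: np.ndarray
    mz_frac_map: np.ndarray
    roi_means: "object" = field(default=None, repr=False)  # pandas.DataFrame

    def time_constant_map(self, modality: str) -> np.ndarray:
        maps = {
            "t1rho": self.t1rho_map,
            "t2rho": self.t2rho_map,
            "raff4": self.traff4_map,
        }
        if modality not in maps:
            raise ValueError(f"no ground-truth map for modality {modality!r}")
        if maps[modality] is None:
            have = sorted(k for k, v in maps.items() if v is not None)
            raise ValueError(
                f"schedule modality {modality!r} does not match ground truth "
                f"(available: {have})"
            )
        return maps[modality]


def generate_phantom(spec, cohort, subject_index: int):
    """Labelled volume plus per-voxel ground truth for one cohort subject.

    Voxel values within an ROI are the subject-level ROI mean (control mean
    + group effect + age slope + between-subject deviate, drawn by the
    cohort module) modulated by a small multiplicative within-ROI texture.
    Deterministic given ``cohort.seed`` and ``subject_index``.
    """
    from rotorelax.synth import cohort as cohort_mod

    labels = spec.rasterize()
    means = cohort_mod.subject_roi_means(cohort, subject_index)
    rng = cohort_mod.subject_rng(cohort.seed, subject_index, "texture")

    shape = spec.grid_shape
    maps = {
        "T1rho": np.full(shape, np.nan),
        "T2rho": np.full(shape, np.nan),
        "RAFF4": np.full(shape, np.nan),
    }
    m0 = np.full(shape, np.nan)
    mss = np.full(shape, np.nan)
    mz = np.full(shape, np.nan)

    lookup = spec.label_lookup()
    mean_of = {(r, m): v for r, m, v in
               means[["roi_name", "metric_name", "value"]].itertuples(index=False)}
    for roi_name, labs in lookup.items():
        sel = np.isin(labels, labs)
        n = int(sel.sum())
        for metric, vol in maps.items():
            texture = 1.0 + cohort.texture_sd * rng.standard_normal(n)
            vol[sel] = mean_of[(roi_name, metric)] * np.clip(texture, 0.05, None)
        m0[sel] = cohort.m0 * (1.0 + cohort.texture_sd * rng.standard_normal(n))
        mss[sel] = cohort.mss_frac
        mz[sel] = cohort.mz_frac
    truth = GroundTruth(maps["T1rho"], maps["T2rho"], maps["RAFF4"],
                        m0, mss, mz, roi_means=means)
    return labels, truth
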