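"""Cohort sampling: demographics, subject-level ROI metric means, bundles.

A subject's true mean for metric *m* in ROI *r* is

    mu = control_mean(r, m) + group_effect(g, r, m)
         + age_slope(m) * (age - age_ref) + cv(m)/100 * control_mean * z

with z a standard-normal between-subject deviate.  The control group is,
by default, ~9 years younger than both patient groups, reproducing the age
confound that the statistics stage must be able to adjust away.  Group
effects default to the qualitative direction of the study findings (e.g.
longer amygdalar T1rho in PD, weaker accumbens network in iRBD) with
user-settable magnitudes, since per-ROI patient means are not published in
the main text.

FA/MD ROI values are drawn directly at this level (diffusion preprocessing
and tensor fitting are out of scope); the relaxation and functional metrics
additionally drive the image-level generators.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "METRICS",
    "FUNCTIONAL_METRICS",
    "GROUPS",
    "CONTROL_ROI_MEANS",
    "RELAX_RANGES",
    "CohortSpec",
    "default_cohort_spec",
    "default_group_effects",
    "subject_rng",
    "demographics_table",
    "subject_roi_means",
    "sample_cohort_table",
    "SubjectBundle",
    "generate_cohort",
]

GROUPS = ("control", "iRBD", "PD")
METRICS = ("T1rho", "T2rho", "RAFF4", "FA", "MD", "network_strength", "ReHo")
FUNCTIONAL_METRICS = ("network_strength", "ReHo")

# Control-group ROI means.  Relaxation times (ms) sit inside the physiologic
# 3 T gray-matter ranges: T1rho 130-180, T2rho 55-90, RAFF4 240-410.
# FA is unitless, MD in mm^2/s, network strength in Z units, ReHo in
# standardized (z-score) units.
CONTROL_ROI_MEANS: dict[str, dict[str, float]] = {
    #                T1rho T2rho RAFF4   FA      MD    net_s  ReHo
    "accumbens":   dict(T1rho=140.0, T2rho=58.0, RAFF4=250.0, FA=0.30, MD=7.2e-4, network_strength=3.0, ReHo=0.30),
    "amygdala":    dict(T1rho=150.0, T2rho=75.0, RAFF4=300.0, FA=0.28, MD=7.8e-4, network_strength=2.8, ReHo=0.35),
    "caudate":     dict(T1rho=135.0, T2rho=60.0, RAFF4=260.0, FA=0.26, MD=7.0e-4, network_strength=3.4, ReHo=0.45),
    "hippocampus": dict(T1rho=155.0, T2rho=78.0, RAFF4=320.0, FA=0.27, MD=8.5e-4, network_strength=3.2, ReHo=0.40),
    "pallidum":    dict(T1rho=132.0, T2rho=56.0, RAFF4=245.0, FA=0.42, MD=6.8e-4, network_strength=2.6, ReHo=0.30),
    "putamen":     dict(T1rho=138.0, T2rho=62.0, RAFF4=270.0, FA=0.31, MD=7.0e-4, network_strength=3.5, ReHo=0.50),
    "thalamus":    dict(T1rho=145.0, T2rho=68.0, RAFF4=290.0, FA=0.36, MD=7.4e-4, network_strength=3.6, ReHo=0.55),
    "midbrain":    dict(T1rho=160.0, T2rho=72.0, RAFF4=340.0, FA=0.44, MD=7.6e-4, network_strength=2.4, ReHo=0.25),
    "pons":        dict(T1rho=165.0, T2rho=80.0, RAFF4=360.0, FA=0.47, MD=7.3e-4, network_strength=2.2, ReHo=0.20),
    "SNc":         dict(T1rho=170.0, T2rho=85.0, RAFF4=380.0, FA=0.43, MD=7.1e-4, network_strength=2.5, ReHo=0.28),
    "SNr":         dict(T1rho=175.0, T2rho=88.0, RAFF4=400.0, FA=0.45, MD=7.0e-4, network_strength=2.4, ReHo=0.26),
}

#: Between-subject coefficient of variation per metric, percent, among
#: controls.  Relaxation metrics are highly reproducible (3%); diffusion and
#: functional metrics progressively less so (9/4/22/35%).
DEFAULT_CV = {
    "T1rho": 3.0, "T2rho": 3.0, "RAFF4": 3.0,
    "FA": 9.0, "MD": 4.0,
    "network_strength": 22.0, "ReHo": 35.0,
}

#: Change per year of age, in each metric's units.  Relaxation times
#: lengthen with age; connectivity metrics decline.
DEFAULT_AGE_SLOPES = {
    "T1rho": 1.0, "T2rho": 0.35, "RAFF4": 1.8,
    "FA": -1.5e-3, "MD": 3.0e-6,
    "network_strength": -0.03, "ReHo": -0.010,
}

#: Group age distributions (mean, SD) in years: controls ~9 y younger.
DEFAULT_AGE_DIST = {
    "control": (57.3, 5.2),
    "iRBD": (65.7, 6.7),
    "PD": (66.1, 6.6),
}

#: Physiologic ranges of the rotating-frame relaxation times in gray
#: matter at 3 T, ms.  Control-group ROI means are drawn inside these.
RELAX_RANGES = {
    "T1rho": (130.0, 180.0),
    "T2rho": (55.0, 90.0),
    "RAFF4": (240.0, 410.0),
}

#: Mean framewise displacement (mean, SD) in mm per group.
DEFAULT_FD_DIST = {
    "control": (0.15, 0.06),
    "iRBD": (0.22, 0.05),
    "PD": (0.18, 0.04),
}


def default_group_effects() -> dict[tuple[str, str, str], float]:
    """Direction-only default effects keyed by (group, roi, metric).

    Signs follow the study's qualitative findings; magnitudes are modest,
    plausible choices (the per-ROI patient means are not published).
    """
    eff: dict[tuple[str, str, str], float] = {}
    pd_t1 = {"amygdala": 12.0, "SNc": 8.0, "hippocampus": 6.0,
             "pons": 6.0, "putamen": 6.0, "thalamus": 6.0}
    for roi, d in pd_t1.items():
        eff[("PD", roi, "T1rho")] = d
    eff[("PD", "amygdala", "T2rho")] = 4.0
    eff[("PD", "thalamus", "T2rho")] = 3.0
    eff[("PD", "SNc", "ReHo")] = -0.15
    eff[("PD", "SNr", "ReHo")] = -0.20
    eff[("PD", "amygdala", "ReHo")] = -0.12
    eff[("PD", "accumbens", "network_strength")] = -0.7
    eff[("PD", "amygdala", "network_strength")] = -0.5
    eff[("PD", "SNr", "network_strength")] = -0.5
    irbd_t1 = {"amygdala": 8.0, "hippocampus": 5.0, "midbrain": 5.0,
               "pons": 5.0, "thalamus": 5.0}
    for roi, d in irbd_t1.items():
        eff[("iRBD", roi, "T1rho")] = d
    eff[("iRBD", "midbrain", "T2rho")] = 5.0
    eff[("iRBD", "midbrain", "RAFF4")] = 25.0
    eff[("iRBD", "SNr", "MD")] = 4.0e-5
    eff[("iRBD", "accumbens", "network_strength")] = -0.9
    return eff


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition, effect structure and noise levels."""

    n_per_group: tuple[int, int, int] = (10, 8, 9)
    group_effects: dict = field(default_factory=default_group_effects)
    age_dist: dict = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    age_slopes: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPES))
    between_subject_cv: dict = field(default_factory=lambda: dict(DEFAULT_CV))
    age_ref: float = 57.3
    noise_sd: float = 1.0       # relaxation-series noise (signal units; M0=100)
    texture_sd: float = 0.01    # within-ROI multiplicative texture (fraction)
    m0: float = 100.0
    mss_frac: float = 0.30
    mz_frac: float = 0.90
    fd_dist: dict = field(default_factory=lambda: dict(DEFAULT_FD_DIST))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(int(n) < 0 for n in self.n_per_group):
            raise ValueError("n_per_group must be three non-negative counts")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.mss_frac < 1):
            raise ValueError("mss_frac must lie in (0, 1)")
        if not (0 < self.mz_frac <= 1):
            raise ValueError("mz_frac must lie in (0, 1]")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))


def default_cohort_spec(**overrides) -> CohortSpec:
    return replace(CohortSpec(), **overrides) if overrides else CohortSpec()


def subject_rng(seed: int, subject_index: int, stage: str) -> np.random.Generator:
    """Deterministic per-subject, per-stage generator.

    The stage name is hashed (CRC32) into the seed sequence so every stage
    draws an independent, reproducible stream regardless of cohort size or
    call order.
    """
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(subject_index), key])
    )


def demographics_table(cohort: CohortSpec) -> pd.DataFrame:
    """Subject id, group, age, sex — deterministic for a given seed.

    Sex is generated so the table mirrors a realistic cohort sheet; no
    downstream metric depends on it.
    """
    rows = []
    idx = 0
    for group, n in zip(GROUPS, cohort.n_per_group):
        mu, sd = cohort.age_dist[group]
        for _ in range(int(n)):
            rng = subject_rng(cohort.seed, idx, "demographics")
            age = float(mu + sd * rng.standard_normal())
            sex = "M" if rng.random() < 0.55 else "F"
            rows.append(
                {"subject_id": f"sub-{idx + 1:02d}", "group": group,
                 "age": round(age, 1), "sex": sex}
            )
            idx += 1
    return pd.DataFrame(rows)


def subject_roi_means(
    cohort: CohortSpec, subject_index: int, demo: pd.DataFrame | None = None
) -> pd.DataFrame:
    """True ROI x metric means for one subject (long format).

    Control-group relaxation times are drawn from the truncated
    distribution confined to the physiologic population range (with a 2%
    interior margin so voxel-averaged estimates stay inside it too): the
    between-subject deviate is redrawn until the value falls in range.
    """
    if demo is None:
        demo = demographics_table(cohort)
    if not 0 <= subject_index < len(demo):
        raise IndexError(
            f"subject_index {subject_index} outside cohort of {len(demo)}"
        )
    row = demo.iloc[subject_index]
    rng = subject_rng(cohort.seed, subject_index, "roi_means")
    out = []
    for roi, base in CONTROL_ROI_MEANS.items():
        for metric in METRICS:
            ctrl = base[metric]
            eff = cohort.group_effects.get((row["group"], roi, metric), 0.0)
            slope = cohort.age_slopes.get(metric, 0.0)
            cv = cohort.between_subject_cv.get(metric, 0.0)
            fixed = ctrl + eff + slope * (row["age"] - cohort.age_ref)
            val = fixed + cv / 100.0 * ctrl * rng.standard_normal()
            if row["group"] == "control" and metric in RELAX_RANGES:
                lo, hi = RELAX_RANGES[metric]
                pad = 0.02 * (hi - lo)
                for _ in range(200):
                    if lo + pad <= val <= hi - pad:
                        break
                    val = fixed + cv / 100.0 * ctrl * rng.standard_normal()
                else:
                    val = float(np.clip(val, lo + pad, hi - pad))
            out.append(
                {"subject_id": row["subject_id"], "group": row["group"],
                 "age": row["age"], "sex": row["sex"],
                 "roi_name": roi, "metric_name": metric, "value": float(val)}
            )
    return pd.DataFrame(out)


def sample_cohort_table(cohort: CohortSpec) -> pd.DataFrame:
    """Long-format cohort table of true subject-level ROI metrics.

    This table-level route drives the group-statistics stage directly (and
    its calibration simulations) without rendering images; the image-level
    generators consume the same subject means, so the two routes agree by
    construction.  A per-subject mean framewise displacement column is
    included as the motion covariate for the functional metrics.
    """
    if min(cohort.n_per_group) < 1:
        # still produce whatever groups exist; downstream stats validate sizes
        pass
    frames = []
    demo = demographics_table(cohort)
    for i in range(len(demo)):
        sub = subject_roi_means(cohort, i, demo)
        rng = subject_rng(cohort.seed, i, "fd")
        mu, sd = cohort.fd_dist[demo.iloc[i]["group"]]
        sub["FD"] = max(float(mu + sd * rng.standard_normal()), 0.01)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SubjectBundle:
    """Everything the pipeline needs for one subject."""

    subject_id: str
    group: str
    age: float
    sex: str
    labels: np.ndarray
    truth: "object"          # GroundTruth
    relax_series: dict       # modality -> 4-D array (raff4 -> (decay, recovery))
    bold: "object"           # BoldSim
    fd_mean: float


def generate_cohort(
    cohort: CohortSpec, phantom, fmri, with_bold: bool = True
) -> Iterator[SubjectBundle]:
    """Yield per-subject data bundles (lazily, one subject in memory at a time)."""
    from rotorelax import relaxometry as rx
    from rotorelax.synth.bold import simulate_bold
    from rotorelax.synth.phantom import generate_phantom
    from rotorelax.synth.relaxation import simulate_relaxation_series

    demo = demographics_table(cohort)
    schedules = {
        "t1rho": rx.T1RHO_SCHEDULE,
        "t2rho": rx.T2RHO_SCHEDULE,
        "raff4": rx.RAFF4_SCHEDULE,
    }
    for i, row in demo.iterrows():
        labels, truth = generate_phantom(phantom, cohort, i)
        series = {}
        for modality, sched in schedules.items():
            sub_seed = subject_rng(cohort.seed, i, f"series-{modality}")
            series[modality] = simulate_relaxation_series(
                truth, sched, cohort.noise_sd, rng=sub_seed
            )
        bold = None
        fd_mean = 0.0
        if with_bold:
            bold = simulate_bold(
                labels, phantom.label_lookup(), fmri,
                rng=subject_rng(cohort.seed, i, "bold"),
            )
            from rotorelax.connectivity import framewise_displacement

            fd_mean = float(np.mean(framewise_displacement(bold.motion)))
        yield SubjectBundle(
            subject_id=row["subject_id"], group=row["group"],
            age=float(row["age"]), sex=row["sex"],
            labels=labels, truth=truth, relax_series=series,
            bold=bold, fd_mean=fd_mean,
        )
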