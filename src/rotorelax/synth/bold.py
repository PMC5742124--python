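"""Resting-state BOLD simulation with planted network structure.

Each planted network is a latent band-limited (0.01-0.1 Hz) time course
shared, scaled by its amplitude, by every voxel of its member ROIs.  On top
of that every voxel carries AR(1) noise and a random quadratic drift; white
matter and CSF boxes carry their own shared nuisance signals (the targets
of aCompCor); and the rigid-body motion trace mixes a smooth low-amplitude
baseline with injected translation spikes whose parameter-derivative norm
exceeds the 0.33 mm censoring threshold.

Under this additive model, two voxels sharing a latent of amplitude ``a``
on unit-variance noise correlate at r = a^2 / (a^2 + sigma^2), which the
tests use as a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = ["FMRISpec", "BoldSim", "default_fmri_spec", "simulate_bold"]

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class FMRISpec:
    n_volumes: int = 502
    tr: float = 0.9
    #: (network name, member ROI names, latent amplitude)
    networks: tuple[tuple[str, tuple[str, ...], float], ...] = (
        ("reward", ("accumbens", "pallidum"), 1.0),
        ("limbic", ("amygdala", "hippocampus"), 1.0),
        ("nigral", ("SNc", "SNr", "midbrain"), 1.0),
        ("striatothalamic", ("thalamus", "putamen", "caudate"), 1.0),
    )
    band: tuple[float, float] = (0.01, 0.1)
    ar_coefficient: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    spike_fraction: float = 0.02
    spike_size_mm: float = 0.6
    motion_baseline_mm: float = 0.02
    #: white frame-to-frame jitter on the motion parameters; 0.02 mm puts
    #: the mean framewise displacement near the ~0.15 mm seen in compliant
    #: subjects while staying far below the 0.33 mm censoring threshold
    motion_jitter_mm: float = 0.02
    nuisance_amplitude: float = 1.0
    wm_box: Box = ((2, 14), (34, 46), (2, 13))
    csf_box: Box = ((34, 46), (34, 46), (2, 11))

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd < 0 or self.spike_fraction < 0:
            raise ValueError("noise_sd and spike_fraction must be >= 0")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < low < high")


def default_fmri_spec(**overrides) -> FMRISpec:
    from dataclasses import replace

    return replace(FMRISpec(), **overrides) if overrides else FMRISpec()


@dataclass
class BoldSim:
    bold: np.ndarray                 # (x, y, z, t) float32
    motion: np.ndarray               # (t, 6): 3 translations mm, 3 rotations rad
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    latents: dict = field(default_factory=dict)
    nuisance: dict = field(default_factory=dict)
    spike_frames: np.ndarray = field(default_factory=lambda: np.array([], int))


def band_limited_signal(
    n: int, tr: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance signal confined to ``band`` (Hz) on the Fourier grid."""
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError(
            f"no Fourier frequency of an n={n}, TR={tr}s run falls in {band} Hz"
        )
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(keep.sum())
    spec[keep] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    return x / x.std()


def _ar1_noise(shape, phi, sd, rng) -> np.ndarray:
    """AR(1) noise with marginal SD ``sd`` along the last axis."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = rng.standard_normal(shape).astype(np.float32) * np.float32(innov_sd)
    if phi == 0:
        return e
    return lfilter([1.0], [1.0, -phi], e, axis=-1).astype(np.float32)


def _box_mask(shape, box: Box) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    m[x0:x1, y0:y1, z0:z1] = True
    return m


def simulate_bold(
    labels: np.ndarray,
    roi_labels: dict[str, list[int]],
    fmri: FMRISpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    amplitude_scale: float = 1.0,
) -> BoldSim:
    """Simulate one subject's BOLD run on a labelled grid.

    ``amplitude_scale`` multiplies every network amplitude, which lets a
    cohort generator weaken a subject's (or group's) networks without
    touching the spec.
    """
    gen = rng if rng is not None else np.random.default_rng(seed)
    labels = np.asarray(labels)
    shape = labels.shape
    n = fmri.n_volumes

    bold = _ar1_noise(shape + (n,), fmri.ar_coefficient, fmri.noise_sd, gen)

    # quadratic drift, random per voxel
    x = np.linspace(-1.0, 1.0, n)
    basis = np.stack([x, 0.5 * (3 * x**2 - 1)])  # Legendre P1, P2
    coef = gen.standard_normal(shape + (2,)).astype(np.float32) * np.float32(
        fmri.drift_amplitude
    )
    bold += np.tensordot(coef, basis.astype(np.float32), axes=([3], [0]))

    latents: dict[str, np.ndarray] = {}
    for name, members, amp in fmri.networks:
        lat = band_limited_signal(n, fmri.tr, fmri.band, gen)
        latents[name] = lat
        a = amp * amplitude_scale
        if a == 0:
            continue
        for roi in members:
            if roi not in roi_labels:
                raise ValueError(
                    f"network {name!r} member ROI {roi!r} not in the label lookup"
                )
            sel = np.isin(labels, roi_labels[roi])
            if not sel.any():
                raise ValueError(
                    f"network {name!r} member ROI {roi!r} has no voxels in labels"
                )
            bold[sel] += np.float32(a) * lat.astype(np.float32)

    wm_mask = _box_mask(shape, fmri.wm_box)
    csf_mask = _box_mask(shape, fmri.csf_box)
    for m, which in ((wm_mask, "wm_box"), (csf_mask, "csf_box")):
        if (labels[m] != 0).any():
            raise ValueError(f"{which} overlaps labelled ROIs; move the box")
    nuisance = {}
    for mask_, key in ((wm_mask, "wm"), (csf_mask, "csf")):
        ts = band_limited_signal(n, fmri.tr, (1.0 / (n * fmri.tr), 0.5 / fmri.tr), gen)
        nuisance[key] = ts
        bold[mask_] += np.float32(fmri.nuisance_amplitude) * ts.astype(np.float32)

    motion, spikes = _simulate_motion(fmri, n, gen)
    return BoldSim(bold, motion, wm_mask, csf_mask, latents, nuisance, spikes)


def _simulate_motion(fmri: FMRISpec, n: int, gen: np.random.Generator):
    t = np.arange(n)
    motion = np.zeros((n, 6))
    for j in range(6):
        cycles = gen.uniform(1.0, 3.0)
        phase = gen.uniform(0, 2 * np.pi)
        amp = fmri.motion_baseline_mm if j < 3 else fmri.motion_baseline_mm / 50.0
        jit = fmri.motion_jitter_mm if j < 3 else fmri.motion_jitter_mm / 50.0
        motion[:, j] = amp * np.sin(2 * np.pi * cycles * t / n + phase)
        motion[:, j] += jit * gen.standard_normal(n)
    n_spikes = int(round(fmri.spike_fraction * n))
    if n_spikes > 0:
        # spikes are kept >= 2 frames apart so each one's derivative norm
        # exceeds the censoring threshold on its own
        candidates = list(range(12, n - 1))  # clear of dropped lead-in frames
        chosen: list[int] = []
        for f in gen.permutation(candidates):
            if all(abs(f - c) >= 2 for c in chosen):
                chosen.append(int(f))
            if len(chosen) == n_spikes:
                break
        spikes = np.sort(np.array(chosen, dtype=int))
        # single-frame translation excursion: the derivative norm exceeds the
        # censoring threshold at the spike frame and the one after it
        motion[spikes, 0] += fmri.spike_size_mm
    else:
        spikes = np.array([], dtype=int)
    return motion, spikes
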