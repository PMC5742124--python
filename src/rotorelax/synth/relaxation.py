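"""Forward simulation of relaxation-weighted image series.

T1rho/T2rho series decay mono-exponentially from M0; RAFF4 produces a
paired decay/recovery set relaxing toward the steady-state magnetization
Mss (the recovery curve starts from the inverted state -Mz).  Noise is
additive i.i.d. Gaussian: the magnitude bias of Rician noise is negligible
at the SNR of the fitted time points and is deliberately not modelled.
"""

from __future__ import annotations

import numpy as np

from rotorelax.relaxometry import AcquisitionSchedule

__all__ = ["simulate_relaxation_series"]


def _resolve_rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def simulate_relaxation_series(
    truth,
    schedule: AcquisitionSchedule,
    noise_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Noisy 4-D series at the schedule's evolution times.

    Returns one (x, y, z, t) array for the mono-exponential modalities and a
    ``(decay, recovery)`` pair for RAFF4.  Voxels without ground truth (NaN
    maps, i.e. outside all ROIs) emit zero signal plus noise.  Reproducible
    given a fixed ``seed`` (or an explicit ``rng``).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t_map = truth.time_constant_map(schedule.modality)  # raises on mismatch
    times = schedule.times_ms()
    gen = _resolve_rng(seed, rng)

    m0 = np.nan_to_num(truth.m0_map, nan=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        decay_kernel = np.exp(-times[None, None, None, :] / t_map[..., None])
    decay_kernel = np.nan_to_num(decay_kernel, nan=0.0)

    if schedule.modality in ("t1rho", "t2rho"):
        signal = m0[..., None] * decay_kernel
        if noise_sd > 0:
            signal = signal + gen.normal(0.0, noise_sd, size=signal.shape)
        return signal

    # RAFF4: relax toward Mss from M0 (decay) and from -Mz (recovery)
    mss = np.nan_to_num(truth.mss_frac_map, nan=0.0) * m0
    mz = np.nan_to_num(truth.mz_frac_map, nan=0.0) * m0
    decay = mss[..., None] + (m0 - mss)[..., None] * decay_kernel
    recovery = mss[..., None] - (mz + mss)[..., None] * decay_kernel
    inside = np.isfinite(t_map)
    decay[~inside] = 0.0
    recovery[~inside] = 0.0
    if noise_sd > 0:
        decay = decay + gen.normal(0.0, noise_sd, size=decay.shape)
        recovery = recovery + gen.normal(0.0, noise_sd, size=recovery.shape)
    return decay, recovery
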