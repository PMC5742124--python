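"""Resting-state connectivity: motion indices, censoring, nuisance
regression, smoothness normalization, seed-based FC and regional homogeneity.

The degrees-of-freedom bookkeeping follows censored regression semantics:
frames whose motion-parameter derivative norm exceeds the threshold are
removed (together with the preceding frame) from both data and regressors,
and the remaining DOF is the number of kept frames minus the rank of the
nuisance design restricted to those frames.  Seed-based correlations are
converted to standard scores by dividing the Fisher-transformed r by the
standard error of the Fisher distribution:

    Z = arctanh(r) * sqrt(DOF - 3)

so that subjects with different amounts of censoring are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "CensorMask",
    "NuisanceDesign",
    "FCMap",
    "NetworkMask",
    "ReHoMap",
    "framewise_displacement",
    "motion_derivative_norm",
    "censor_mask",
    "nuisance_design",
    "denoise",
    "estimate_fwhm",
    "smooth_to_fwhm",
    "fisher_z",
    "seed_fc",
    "define_network",
    "network_strength",
    "kendall_w",
    "reho",
]

logger = logging.getLogger(__name__)

#: Sphere radius (mm) used to convert rotations to arc length, both for FD
#: and for the censoring derivative norm.
SPHERE_RADIUS_MM = 50.0

#: Default censoring threshold on the motion derivative norm, mm.
CENSOR_THRESHOLD_MM = 0.33

#: Minimum residual DOF for a subject to enter the connectivity analysis.
MIN_DOF = 20


def _check_motion(motion: np.ndarray) -> np.ndarray:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (n_frames, 6)")
    if motion.shape[0] < 2:
        raise ValueError("motion trace needs >= 2 frames")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters must be finite")
    return motion


def framewise_displacement(
    motion: np.ndarray, sphere_radius: float = SPHERE_RADIUS_MM
) -> np.ndarray:
    """Power-style FD: summed absolute backward differences, rotations
    converted to arc length on a ``sphere_radius`` sphere.  FD of the first
    frame is 0 by convention."""
    motion = _check_motion(motion)
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + sphere_radius * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def motion_derivative_norm(
    motion: np.ndarray, sphere_radius: float = SPHERE_RADIUS_MM
) -> np.ndarray:
    """Euclidean norm of the 6 motion-parameter backward differences (mm)."""
    motion = _check_motion(motion)
    d = np.diff(motion, axis=0)
    d = np.column_stack([d[:, :3], sphere_radius * d[:, 3:]])
    return np.concatenate([[0.0], np.sqrt((d**2).sum(axis=1))])


@dataclass
class CensorMask:
    keep: np.ndarray            # boolean per frame
    n_kept: int
    dof_remaining: int | None   # None when no design was supplied
    excluded: bool = False      # True when dof_remaining < MIN_DOF

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)


def censor_mask(
    motion: np.ndarray,
    threshold: float = CENSOR_THRESHOLD_MM,
    design: "NuisanceDesign | np.ndarray | None" = None,
    sphere_radius: float = SPHERE_RADIUS_MM,
    min_dof: int = MIN_DOF,
) -> CensorMask:
    """Flag frames whose motion-derivative norm exceeds ``threshold``,
    together with each previous frame (set union, overlap safe).

    With a nuisance ``design``, the remaining DOF (kept frames minus the
    rank of the design restricted to kept frames) is computed, and the
    subject is marked ``excluded`` when it falls below ``min_dof``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    norm = motion_derivative_norm(motion, sphere_radius)
    bad = norm > threshold
    bad[:-1] |= bad[1:]  # each previous time point too
    keep = ~bad
    n_kept = int(keep.sum())
    dof = None
    excluded = False
    if design is not None:
        x = design.matrix if isinstance(design, NuisanceDesign) else np.asarray(design)
        if x.shape[0] != keep.size:
            raise ValueError(
                f"design has {x.shape[0]} rows but motion has {keep.size} frames"
            )
        rank = int(np.linalg.matrix_rank(x[keep])) if n_kept else 0
        dof = n_kept - rank
        if dof < min_dof:
            excluded = True
            logger.warning(
                "insufficient DOF after censoring: %d kept - rank %d = %d < %d",
                n_kept, rank, dof, min_dof,
            )
    return CensorMask(keep, n_kept, dof, excluded)


@dataclass
class NuisanceDesign:
    """Frames x regressors matrix with labelled column groups."""

    matrix: np.ndarray
    column_groups: list[str]    # one group label per column

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, g in enumerate(self.column_groups) if g == group]
        return self.matrix[:, idx]


def _legendre_basis(n: int, order: int = 2) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    return np.polynomial.legendre.legvander(x, order)


def spectral_regressors(
    n: int, tr: float, band: tuple[float, float] = (0.01, 0.1)
) -> np.ndarray:
    """Sine/cosine pairs at Fourier frequencies outside ``band`` (Hz).

    Frequencies k/(n*TR) for k = 1 .. n//2 with f < band[0] or f > band[1];
    at the Nyquist index of an even-length run the sine is identically zero
    and is omitted.
    """
    t = np.arange(n)
    cols = []
    for k in range(1, n // 2 + 1):
        f = k / (n * tr)
        if band[0] <= f <= band[1]:
            continue
        arg = 2 * np.pi * k * t / n
        cols.append(np.cos(arg))
        if not (n % 2 == 0 and k == n // 2):
            cols.append(np.sin(arg))
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


def _compcor(
    bold: np.ndarray,
    mask: np.ndarray,
    erosion: int,
    n_components: int,
    legendre: np.ndarray,
    name: str,
) -> np.ndarray:
    """First principal-component time courses inside an eroded tissue mask.

    The voxel x time matrix is detrended against the Legendre columns (only)
    before the SVD; zero-variance voxels are dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    if erosion > 0:
        mask = ndimage.binary_erosion(mask, iterations=erosion)
    if not mask.any():
        raise ValueError(
            f"{name} mask is empty after {erosion}-voxel erosion; "
            "use a larger mask or smaller erosion"
        )
    ts = bold[mask].T.astype(float)  # (n_frames, n_voxels)
    ts = ts - ts.mean(axis=0)
    keep = ts.std(axis=0) > 0
    ts = ts[:, keep]
    if ts.shape[1] == 0:
        raise ValueError(f"{name} mask contains only zero-variance voxels")
    # remove slow drift so components capture physiological noise, not trend
    proj = legendre @ np.linalg.lstsq(legendre, ts, rcond=None)[0]
    ts = ts - proj
    u, s, _ = np.linalg.svd(ts, full_matrices=False)
    k = min(n_components, u.shape[1])
    return u[:, :k]


def nuisance_design(
    motion: np.ndarray,
    bold: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    tr: float,
    band: tuple[float, float] = (0.01, 0.1),
    n_compcor: int = 5,
    wm_erosion: int = 2,
    csf_erosion: int = 1,
) -> NuisanceDesign:
    """Full nuisance model: Legendre 0-2, out-of-band sines/cosines, six
    motion parameters and their backward-difference derivatives, and five
    aCompCor components from each of the eroded WM and CSF masks."""
    motion = _check_motion(motion)
    n = motion.shape[0]
    if bold.shape[-1] != n:
        raise ValueError(
            f"bold has {bold.shape[-1]} frames but motion has {n}"
        )
    leg = _legendre_basis(n)
    spec = spectral_regressors(n, tr, band)
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    wm_pc = _compcor(bold, wm_mask, wm_erosion, n_compcor, leg, "WM")
    csf_pc = _compcor(bold, csf_mask, csf_erosion, n_compcor, leg, "CSF")
    blocks = [
        ("legendre", leg),
        ("spectral", spec),
        ("motion", motion),
        ("motion_derivative", deriv),
        ("wm_compcor", wm_pc),
        ("csf_compcor", csf_pc),
    ]
    matrix = np.column_stack([b for _, b in blocks])
    groups: list[str] = []
    for name, b in blocks:
        groups.extend([name] * b.shape[1])
    return NuisanceDesign(matrix, groups)


def denoise(
    bold: np.ndarray,
    design: NuisanceDesign | np.ndarray,
    censor: CensorMask | None = None,
) -> tuple[np.ndarray, int]:
    """Regress the nuisance design out of the BOLD series on kept frames.

    Returns the residual series containing only the kept frames, plus the
    remaining DOF (kept frames minus design rank).  Rank-deficient designs
    are handled by a pseudoinverse solve, which is equivalent to dropping
    collinear columns; a warning is logged.
    """
    x_full = design.matrix if isinstance(design, NuisanceDesign) else np.asarray(design)
    n = bold.shape[-1]
    if x_full.shape[0] != n:
        raise ValueError(f"design rows {x_full.shape[0]} != bold frames {n}")
    keep = censor.keep if censor is not None else np.ones(n, dtype=bool)
    y = bold.reshape(-1, n).T[keep].astype(float)  # (kept, voxels)
    x = x_full[keep]
    rank = int(np.linalg.matrix_rank(x))
    if rank < x.shape[1]:
        logger.warning(
            "nuisance design rank deficient (%d < %d columns); collinear "
            "columns are effectively dropped", rank, x.shape[1],
        )
    beta = np.linalg.pinv(x) @ y
    resid = (y - x @ beta).T.reshape(bold.shape[:-1] + (int(keep.sum()),))
    return resid, int(keep.sum()) - rank


def estimate_fwhm(data: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Gradient-based global smoothness estimate, per spatial axis, in mm.

    Assumes a Gaussian spatial autocorrelation: the ratio of the mean
    squared first difference to twice the variance gives 1 - rho(1), from
    which the Gaussian ACF width and hence the FWHM follow.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    out = np.full(3, np.nan)
    var = data.var(axis=(0, 1, 2)).mean()
    if var == 0:
        return out
    for ax in range(3):
        vdiff = np.mean(np.diff(data, axis=ax) ** 2)
        ratio = vdiff / (2.0 * var)
        if not (0 < ratio < 1):
            continue
        sigma2 = -1.0 / (4.0 * np.log(1.0 - ratio))
        out[ax] = 2.0 * np.sqrt(2.0 * np.log(2.0)) * np.sqrt(sigma2) * voxel_size_mm[ax]
    return out


def smooth_to_fwhm(
    bold: np.ndarray, target_fwhm_mm: float, voxel_size_mm
) -> np.ndarray:
    """Bring the series to an isotropic target smoothness by convolving with
    the Gaussian whose width makes up the difference from the estimated
    intrinsic smoothness (sigma_add^2 = sigma_target^2 - sigma_intrinsic^2).

    A target of 0 is the identity; a target below the estimated intrinsic
    smoothness logs a warning and returns the input unchanged.
    """
    if target_fwhm_mm == 0:
        return bold
    if target_fwhm_mm < 0:
        raise ValueError("target FWHM must be >= 0")
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2.3548 sigma
    intrinsic = estimate_fwhm(bold, voxel_size_mm)
    intrinsic = np.where(np.isfinite(intrinsic), intrinsic, 0.0)
    if np.all(intrinsic >= target_fwhm_mm):
        logger.warning(
            "target FWHM %.2f mm below estimated intrinsic smoothness %s; no-op",
            target_fwhm_mm, np.round(intrinsic, 2),
        )
        return bold
    sig_t = target_fwhm_mm / factor
    sig_i = intrinsic / factor
    sig_add_mm = np.sqrt(np.clip(sig_t**2 - sig_i**2, 0.0, None))
    sigma_vox = sig_add_mm / voxel_size_mm
    sigma = tuple(sigma_vox) + ((0.0,) if bold.ndim == 4 else ())
    return ndimage.gaussian_filter(bold.astype(float), sigma=sigma)


_R_CLIP = 1.0 - 1e-7


def fisher_z(r, dof: float):
    """DOF-corrected standard score of a correlation:
    ``Z = arctanh(r) * sqrt(DOF - 3)``.  |r| is clipped just below 1."""
    if dof <= 3:
        raise ValueError(f"dof must exceed 3, got {dof}")
    r = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    return np.arctanh(r) * np.sqrt(dof - 3.0)


@dataclass
class FCMap:
    z: np.ndarray
    seed: str
    dof: int
    valid_mask: np.ndarray = None  # voxels with defined correlations


def seed_fc(
    bold: np.ndarray,
    labels: np.ndarray,
    seed_labels,
    dof: int,
    seed_name: str = "",
    brain_mask: np.ndarray | None = None,
) -> FCMap:
    """Seed-based FC: Pearson r of each voxel against the seed-mean time
    course, expressed as the DOF-corrected Z score.  Zero-variance voxels
    get Z = 0 and are flagged out of the validity mask."""
    labels = np.asarray(labels)
    if labels.shape != bold.shape[:-1]:
        raise ValueError(
            f"labels shape {labels.shape} != bold grid {bold.shape[:-1]}"
        )
    sel = np.isin(labels, np.atleast_1d(seed_labels))
    if not sel.any():
        raise ValueError(f"seed ROI {seed_name or seed_labels} has no voxels")
    n = bold.shape[-1]
    seed_ts = bold[sel].mean(axis=0).astype(float)
    seed_ts = seed_ts - seed_ts.mean()
    seed_norm = np.sqrt((seed_ts**2).sum())
    if seed_norm == 0:
        raise ValueError("seed time course has zero variance")
    y = bold.reshape(-1, n).astype(float)
    y = y - y.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((y**2).sum(axis=1))
    valid = y_norm > 0
    r = np.zeros(y.shape[0])
    r[valid] = (y[valid] @ seed_ts) / (y_norm[valid] * seed_norm)
    z = fisher_z(r, dof)
    z[~valid] = 0.0
    shape = bold.shape[:-1]
    if brain_mask is not None:
        valid &= np.asarray(brain_mask, bool).ravel()
    return FCMap(z.reshape(shape), seed_name, int(dof), valid.reshape(shape))


@dataclass
class NetworkMask:
    mask: np.ndarray
    seed: str
    alpha: float
    min_cluster: int


def define_network(
    control_z_maps,
    alpha: float = 0.0005,
    min_cluster: int = 20,
    seed_name: str = "",
) -> NetworkMask:
    """Control-group network: voxelwise one-sample, one-tailed (positive)
    t-test on the Z maps thresholded at ``alpha``, then connected components
    smaller than ``min_cluster`` voxels (6-connectivity) are discarded."""
    arrs = [m.z if isinstance(m, FCMap) else np.asarray(m) for m in control_z_maps]
    if len(arrs) < 3:
        raise ValueError("need at least 3 control maps")
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"control maps on different grids: {sorted(shapes)}")
    stack = np.stack(arrs)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = stats.t.sf(t, df=n - 1)
    p = np.where(sd == 0, np.where(mean > 0, 0.0, 1.0), p)
    sig = p < alpha
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    lab, n_comp = ndimage.label(sig, structure=structure)
    mask = np.zeros_like(sig)
    for c in range(1, n_comp + 1):
        comp = lab == c
        if comp.sum() >= min_cluster:
            mask |= comp
    if not mask.any():
        logger.warning("network mask for seed %r is empty", seed_name)
    return NetworkMask(mask, seed_name, alpha, min_cluster)


def network_strength(z_map: FCMap | np.ndarray, network: NetworkMask | np.ndarray):
    """Mean Z inside the control-defined network; NaN for an empty network."""
    z = z_map.z if isinstance(z_map, FCMap) else np.asarray(z_map)
    m = network.mask if isinstance(network, NetworkMask) else np.asarray(network, bool)
    if not m.any():
        logger.warning("network strength undefined: empty network mask")
        return float("nan")
    return float(z[m].mean())


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance among the rows of ``series``
    (m series x n time points), with mid-ranks and the standard tie
    correction:  W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be 2-D (m series x n time points)")
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 series and 2 time points")
    ranks = stats.rankdata(x, axis=1)
    rsum = ranks.sum(axis=0)
    s = ((rsum - rsum.mean()) ** 2).sum()
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        return float("nan")
    return float(12.0 * s / denom)


def _neighborhood_offsets() -> list[tuple[int, int, int]]:
    """The 18 nearest neighbors: face- and edge-adjacent voxels."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                nab = abs(dx) + abs(dy) + abs(dz)
                if nab in (1, 2):
                    offs.append((dx, dy, dz))
    assert len(offs) == 18
    return offs


def _shift(arr: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    """Shift a (possibly 4-D) array spatially, filling with zeros."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for d, o in enumerate(off):
        n = arr.shape[d]
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


@dataclass
class ReHoMap:
    z: np.ndarray           # standardized map (mean 0, SD 1 over valid mask)
    w: np.ndarray           # raw Kendall's W
    valid_mask: np.ndarray


def reho(bold: np.ndarray, mask: np.ndarray, min_neighbors: int = 2) -> ReHoMap:
    """Regional homogeneity: Kendall's W among each in-mask voxel's time
    series and those of its (up to) 18 in-mask nearest neighbors, then
    standardized to z-scores over the brain mask.

    Voxels with fewer than ``min_neighbors`` in-mask neighbors are masked
    out.  The computation is rank-based, so any strictly monotone transform
    applied uniformly within a neighborhood leaves W unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.shape[:-1]:
        raise ValueError(
            f"mask shape {mask.shape} != bold grid {bold.shape[:-1]}"
        )
    if not mask.any():
        raise ValueError("brain mask is empty")
    n = bold.shape[-1]
    if n < 4:
        raise ValueError("ReHo needs at least 4 time frames")
    ranks = stats.rankdata(np.asarray(bold, float), axis=-1)
    ranks[~mask] = 0.0
    # per-voxel tie correction term T = sum over tie groups (t^3 - t)
    sorted_b = np.sort(np.asarray(bold, float), axis=-1)
    same = np.concatenate(
        [np.zeros(bold.shape[:-1] + (1,), bool),
         np.diff(sorted_b, axis=-1) == 0], axis=-1,
    )
    # run-length encode ties along the last axis
    tie_term = np.zeros(bold.shape[:-1])
    run = np.ones(bold.shape[:-1])
    for t in range(1, n):
        cont = same[..., t]
        run = np.where(cont, run + 1, 1.0)
        # each extension of a tie run adds (r^3 - r) - ((r-1)^3 - (r-1)),
        # which telescopes to r^3 - r over the full run
        prev = run - 1
        tie_term += np.where(cont, (run**3 - run) - (prev**3 - prev), 0.0)

    m_count = mask.astype(float)
    rank_sum = ranks.copy()
    tie_sum = np.where(mask, tie_term, 0.0)
    for off in _neighborhood_offsets():
        rank_sum += _shift(ranks, off + (0,))
        m_count += _shift(mask.astype(float), off)
        tie_sum += _shift(np.where(mask, tie_term, 0.0), off)
    valid = mask & (m_count >= 1 + min_neighbors)

    s = (rank_sum**2).sum(axis=-1) - rank_sum.sum(axis=-1) ** 2 / n
    denom = m_count**2 * (n**3 - n) - m_count * tie_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(valid & (denom > 0), 12.0 * s / denom, np.nan)
    valid &= np.isfinite(w)
    mu = w[valid].mean()
    sd = w[valid].std()
    z = np.full_like(w, np.nan)
    if sd > 0:
        z[valid] = (w[valid] - mu) / sd
    else:
        z[valid] = 0.0
    return ReHoMap(z, w, valid)
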