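"""Acquisition and signal data model for multi-shell diffusion MRI.

Internal unit conventions
-------------------------
b-values are stored in ms/µm² and diffusivities in µm²/ms, so that the fixed
NODDI priors read as their conventional printed values (d∥ = 1.7 µm²/ms,
Diso = 3.0 µm²/ms).  Gradient-table I/O follows the FSL dialect in which
b-values are given in s/mm²; they are divided by 1000 on load and multiplied
back on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ModelConstants",
    "AcquisitionScheme",
    "SignalArray",
    "PowderTable",
    "load_scheme",
    "write_scheme",
    "load_nifti_signals",
    "powder_average",
    "DEFAULT_B0_THRESHOLD",
    "SHELL_ROUNDING",
]

#: default b0 threshold, ms/µm² (= 50 s/mm²)
DEFAULT_B0_THRESHOLD = 0.05
#: shells are distinct b-values after rounding to this grid (ms/µm²)
SHELL_ROUNDING = 0.05


class GradientTableError(ValueError):
    """Malformed or inconsistent .bval/.bvec input."""


@dataclass(frozen=True)
class ModelConstants:
    """Fixed model constants shared across the pipeline.

    d_par
        Intrinsic axonal diffusivity of the neurite compartment, µm²/ms.
    d_iso
        Free-water diffusivity at body temperature, µm²/ms.
    fiso_cutoff
        Free-water fraction above which voxels are treated as degenerate
        CSF-like voxels and excluded from ROI averages (strict inequality).
    outlier_sd
        Number of standard deviations defining participant-level outliers.
    fdr_q
        False-discovery-rate level for the correlation grids.
    """

    d_par: float = 1.7
    d_iso: float = 3.0
    fiso_cutoff: float = 0.9
    outlier_sd: float = 5.0
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if not (self.d_par > 0 and self.d_iso > 0 and self.outlier_sd > 0 and self.fdr_q > 0):
            raise ValueError("model constants must be strictly positive")
        if not 0.0 < self.fiso_cutoff < 1.0:
            raise ValueError("fiso_cutoff must lie in (0, 1)")


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell acquisition: per-volume b-values and unit gradient directions.

    Parameters
    ----------
    bvals
        (n_volumes,) b-values in ms/µm².
    bvecs
        (n_volumes, 3) gradient directions; unit norm on non-b0 volumes
        (b0 rows may be zero).
    b0_threshold
        Volumes with b <= threshold count as b0 (ms/µm²).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientTableError("bvecs must have shape (n_volumes, 3)")
        if bvecs.shape[0] != bvals.size:
            raise GradientTableError(
                f"bval count {bvals.size} != bvec count {bvecs.shape[0]}"
            )
        if not (np.isfinite(bvals).all() and np.isfinite(bvecs).all()):
            raise GradientTableError("non-finite entries in gradient table")
        if (bvals < 0).any():
            raise GradientTableError("negative b-values")
        norms = np.linalg.norm(bvecs[~self.b0_mask], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise GradientTableError(
                "non-b0 gradient directions must be unit vectors (1e-6); "
                "use load_scheme to renormalize raw tables"
            )
        if self.n_b0 == 0:
            raise GradientTableError("scheme must contain at least one b0 volume")

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def shells(self) -> np.ndarray:
        """Distinct non-zero b-values after rounding to the shell grid, ascending."""
        b = self.bvals[~self.b0_mask]
        rounded = np.round(b / SHELL_ROUNDING) * SHELL_ROUNDING
        return np.unique(rounded)

    @property
    def shell_index(self) -> np.ndarray:
        """Per-volume shell id: -1 for b0, otherwise index into ``shells``."""
        idx = np.full(self.n_volumes, -1, dtype=int)
        shells = self.shells
        nb0 = ~self.b0_mask
        rounded = np.round(self.bvals[nb0] / SHELL_ROUNDING) * SHELL_ROUNDING
        idx[nb0] = np.searchsorted(shells, rounded)
        return idx


@dataclass
class SignalArray:
    """Per-voxel diffusion-weighted signals, one column per acquisition volume."""

    values: np.ndarray  # (n_voxels, n_volumes), non-negative

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if (values < 0).any():
            raise ValueError("signal values must be non-negative")
        self.values = values

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    def s0(self, scheme: AcquisitionScheme) -> np.ndarray:
        """Per-voxel S0 estimate: mean over b0 volumes."""
        self._check(scheme)
        return self.values[:, scheme.b0_mask].mean(axis=1)

    def _check(self, scheme: AcquisitionScheme) -> None:
        if self.n_volumes != scheme.n_volumes:
            raise ValueError(
                f"signal has {self.n_volumes} volumes, scheme has {scheme.n_volumes}"
            )


@dataclass
class PowderTable:
    """Direction-averaged (powder) signals: S̄(b) per shell plus S0 per voxel."""

    shell_bvals: np.ndarray  # (n_shells,)
    sbar: np.ndarray         # (n_voxels, n_shells)
    s0: np.ndarray           # (n_voxels,)


def _parse_fsl_table(path: Path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise GradientTableError(f"could not parse {path}: {exc}") from exc
    if not np.isfinite(arr).all():
        raise GradientTableError(f"non-finite entries in {path}")
    return arr


def load_scheme(
    bval_path: str | Path,
    bvec_path: str | Path,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> AcquisitionScheme:
    """Read an FSL-dialect .bval/.bvec pair.

    b-values are converted from s/mm² to ms/µm² (÷1000).  The .bvec file may
    be 3×N (FSL convention, one row per axis) or N×3; the orientation is
    auto-detected.  Non-b0 directions are renormalized to unit length, with a
    warning when the raw norm deviates from 1 by more than 1e-3.
    """
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    bvals = _parse_fsl_table(bval_path).ravel() / 1000.0
    raw = _parse_fsl_table(bvec_path)
    if raw.shape[0] == 3 and raw.shape[1] != 3:
        bvecs = raw.T
    elif raw.shape[1] == 3:
        bvecs = raw
    elif raw.shape[0] == 3:  # ambiguous 3x3: FSL row-per-axis convention
        bvecs = raw.T
    else:
        raise GradientTableError(f"{bvec_path}: expected a 3xN or Nx3 array, got {raw.shape}")
    if bvecs.shape[0] != bvals.size:
        raise GradientTableError(
            f"{bval_path} has {bvals.size} volumes but {bvec_path} has {bvecs.shape[0]}"
        )
    b0_mask = bvals <= b0_threshold
    norms = np.linalg.norm(bvecs, axis=1)
    bad = (~b0_mask) & (np.abs(norms - 1.0) > 1e-3)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} non-b0 direction(s) in {bvec_path} renormalized "
            f"(worst norm {norms[bad].min():.3g})",
            stacklevel=2,
        )
    out = bvecs.copy()
    nb0 = ~b0_mask
    zero = norms < 1e-12
    if (nb0 & zero).any():
        raise GradientTableError("zero-length direction on a non-b0 volume")
    safe = norms.copy()
    safe[zero] = 1.0
    out[nb0] = bvecs[nb0] / safe[nb0, None]
    out[b0_mask & zero] = 0.0
    return AcquisitionScheme(bvals=bvals, bvecs=out, b0_threshold=b0_threshold)


def write_scheme(
    scheme: AcquisitionScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write an FSL-dialect .bval/.bvec pair (s/mm²; 3×N bvec)."""
    np.savetxt(bval_path, scheme.bvals[None, :] * 1000.0, fmt="%.9g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.9f")


def load_nifti_signals(path: str | Path, mask: np.ndarray | None = None) -> SignalArray:
    """Read a 4-D NIfTI into a SignalArray (4th axis = acquisition volumes).

    ``mask`` is an optional boolean 3-D array selecting voxels; otherwise all
    voxels are flattened in C order.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D NIfTI, got shape {data.shape}")
    if mask is not None:
        values = data[np.asarray(mask, dtype=bool)]
    else:
        values = data.reshape(-1, data.shape[-1])
    return SignalArray(values=np.clip(values, 0.0, None))


def powder_average(
    signals: SignalArray,
    scheme: AcquisitionScheme,
    weights: np.ndarray | None = None,
) -> PowderTable:
    """Direction-average signals within each shell (powder averaging).

    S̄(b) is the arithmetic mean of the shell's directional signals and S0 the
    mean over b0 volumes; averaging over directions removes the dependence on
    the fibre orientation distribution.  ``weights`` optionally supplies
    per-volume quadrature weights (normalized within each shell), used by
    synthetic schemes whose directions form a spherical quadrature grid; the
    default is the plain arithmetic mean.
    """
    signals._check(scheme)
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.size != scheme.n_volumes:
            raise ValueError("weights must have one entry per volume")
    shells = scheme.shells
    if shells.size == 0:
        raise ValueError("scheme has no non-zero shell")
    shell_index = scheme.shell_index
    sbar = np.empty((signals.n_voxels, shells.size))
    for k in range(shells.size):
        cols = shell_index == k
        if not cols.any():
            raise ValueError(f"empty shell b={shells[k]}")
        if weights is None:
            sbar[:, k] = signals.values[:, cols].mean(axis=1)
        else:
            w = weights[cols]
            sbar[:, k] = signals.values[:, cols] @ (w / w.sum())
    return PowderTable(shell_bvals=shells, sbar=sbar, s0=signals.s0(scheme))
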