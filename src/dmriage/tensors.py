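"""DTI, mean-signal DKI and full DKI tensor fitting.

Three signal representations are fitted per voxel:

* **DTI** — ``S = S0 exp(-b nᵀDn)``, nonlinear least squares initialized from
  a log-linear fit; supplies FA and the principal fibre direction.
* **MSDKI** — the cumulant expansion of the powder-averaged signal,
  ``log S̄(b)/S0 = -b·MSD + (1/6) b² MSD² MSK``, fitted by weighted linear
  least squares (WLLS).  Because it uses direction-averaged signals, MSD and
  MSK are invariant to crossing/dispersing fibre geometry.
* **DKI** — the 21-parameter directional cumulant expansion
  ``log S = log S0 - b D(n) + (1/6) b² MD² W(n)`` with a fully symmetric
  rank-4 kurtosis tensor W (15 unique elements), also by WLLS, yielding
  MD/RD/AD and MK/RK/AK.

WLLS convention (pinned for reproducibility): weights are the squared
model-predicted signals from an ordinary least-squares first pass, with
exactly one reweighting iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AcquisitionScheme, PowderTable, SignalArray

__all__ = [
    "TensorFit",
    "MSDKIFit",
    "DKIFit",
    "fa_from_eigenvalues",
    "fit_dti",
    "fit_msdki",
    "fit_dki",
    "roi_median_kurtosis",
    "loglinear_dti",
]


@dataclass
class TensorFit:
    """Diffusion tensor fit: tensor, sorted eigenvalues and scalar metrics."""

    D: np.ndarray                 # symmetric 3x3, µm²/ms
    eigenvalues: np.ndarray       # descending (λ1 ≥ λ2 ≥ λ3)
    eigenvectors: np.ndarray      # columns match eigenvalues
    fa: float
    md: float
    rd: float
    ad: float
    s0_fitted: float
    clipped: bool = False

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


@dataclass
class MSDKIFit:
    """Mean-signal diffusivity/kurtosis from powder-averaged shells."""

    msd: float
    msk: float
    s0_fitted: float
    residual_norm: float
    clipped: bool = False
    negative_msk: bool = False


@dataclass
class DKIFit:
    """Full diffusion + kurtosis tensor fit."""

    D: np.ndarray        # 3x3
    W: np.ndarray        # 3x3x3x3 fully symmetric
    md: float
    rd: float
    ad: float
    mk: float
    rk: float
    ak: float
    fa: float
    s0_fitted: float


def fa_from_eigenvalues(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy sqrt(3/2)·||λ-λ̄|| / ||λ||, eigenvalues clipped at 0.

    Returns NaN when all eigenvalues vanish after clipping.
    """
    lam = np.clip(np.asarray([l1, l2, l3], dtype=float), 0.0, None)
    norm2 = float(np.sum(lam**2))
    if norm2 == 0.0:
        return float("nan")
    mean = lam.mean()
    fa = float(np.sqrt(1.5 * np.sum((lam - mean) ** 2) / norm2))
    return min(fa, 1.0)


def _dti_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Design matrix for log-signal: [1, -b·(x², y², z², 2xy, 2xz, 2yz)]."""
    x, y, z = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    cols = np.stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z], axis=1)
    return np.column_stack([np.ones_like(bvals), -bvals[:, None] * cols])


def _tensor_from_coeffs(c: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = c
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def loglinear_dti(
    signals: SignalArray, scheme: AcquisitionScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Log-linear (OLS) tensor fit for all voxels at once.

    Returns ``(tensors, s0)`` with tensors of shape (n_voxels, 3, 3).  Used to
    initialize the nonlinear DTI fit and the NODDI fibre direction.
    """
    signals._check(scheme)
    X = _dti_design(scheme.bvals, scheme.bvecs)
    y = np.log(np.clip(signals.values, 1e-12, None))
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    s0 = np.exp(beta[0])
    tensors = np.empty((signals.n_voxels, 3, 3))
    for v in range(signals.n_voxels):
        tensors[v] = _tensor_from_coeffs(beta[1:, v])
    return tensors, s0


def _select_shells(scheme: AcquisitionScheme, shells_used) -> np.ndarray:
    """Volume mask keeping b0 plus the requested shells (all if None)."""
    if shells_used is None:
        return np.ones(scheme.n_volumes, dtype=bool)
    shells_used = np.atleast_1d(np.asarray(shells_used, dtype=float))
    keep = scheme.b0_mask.copy()
    shells = scheme.shells
    idx = scheme.shell_index
    for b in shells_used:
        k = int(np.argmin(np.abs(shells - b)))
        if abs(shells[k] - b) > 0.05:
            raise ValueError(f"no shell near b={b}")
        keep |= idx == k
    return keep


def fit_dti(
    signals: SignalArray,
    scheme: AcquisitionScheme,
    shells_used=None,
) -> list[TensorFit]:
    """Nonlinear least-squares tensor fit (both shells jointly by default).

    The fit minimizes amplitude residuals ``S0 exp(-b nᵀDn) - S`` starting
    from the log-linear OLS solution.  Negative eigenvalues are clipped to 0
    for FA (flagged via ``clipped``).
    """
    from scipy.optimize import least_squares

    signals._check(scheme)
    keep = _select_shells(scheme, shells_used)
    bvals, bvecs = scheme.bvals[keep], scheme.bvecs[keep]
    sub = SignalArray(signals.values[:, keep])
    if int((bvals > scheme.b0_threshold).sum()) < 6:
        raise ValueError("need at least 6 diffusion-weighted volumes")
    X = _dti_design(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient gradient design (collinear directions)")
    scheme_sub = AcquisitionScheme(bvals, np.where(bvals[:, None] > scheme.b0_threshold, bvecs, 0.0), scheme.b0_threshold)
    tensors0, s00 = loglinear_dti(sub, scheme_sub)

    design_quad = np.einsum("ni,nj->nij", bvecs, bvecs)

    fits: list[TensorFit] = []
    for v in range(sub.n_voxels):
        y = sub.values[v]

        def model(p):
            D = _tensor_from_coeffs(p[1:])
            q = np.einsum("nij,ij->n", design_quad, D)
            return p[0] * np.exp(-bvals * q)

        D0 = tensors0[v]
        p0 = np.array(
            [s00[v], D0[0, 0], D0[1, 1], D0[2, 2], D0[0, 1], D0[0, 2], D0[1, 2]]
        )
        res = least_squares(lambda p: model(p) - y, p0, method="lm", xtol=1e-12, ftol=1e-12)
        D = _tensor_from_coeffs(res.x[1:])
        evals, evecs = np.linalg.eigh(D)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        clipped = bool((evals < 0).any())
        fits.append(
            TensorFit(
                D=D,
                eigenvalues=evals,
                eigenvectors=evecs,
                fa=fa_from_eigenvalues(*evals),
                md=float(evals.mean()),
                rd=float(evals[1:].mean()),
                ad=float(evals[0]),
                s0_fitted=float(res.x[0]),
                clipped=clipped,
            )
        )
    return fits


def _wlls(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-step reweighted linear least squares on log-signals.

    OLS first pass; weights = squared predicted signals; single reweighting
    iteration.
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.exp(X @ beta) ** 2
    Xw = X * w[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return beta


def fit_msdki(powder: PowderTable) -> list[MSDKIFit]:
    """Fit the mean-signal cumulant expansion per voxel by WLLS.

    Regresses log S̄(b) on ``[1, -b, b²/6]`` (including the b0 point), giving
    (log S0, MSD, MSD²·MSK).  Non-positive S̄ points are dropped; fewer than
    three usable points is an error.  MSD is clipped at zero (flagged);
    negative MSK estimates are reported with ``negative_msk`` set, never
    clipped — implausible negative kurtosis is itself a data-quality signal.
    """
    b = np.concatenate([[0.0], powder.shell_bvals])
    X_full = np.column_stack([np.ones_like(b), -b, b**2 / 6.0])
    fits: list[MSDKIFit] = []
    for v in range(powder.sbar.shape[0]):
        s = np.concatenate([[powder.s0[v]], powder.sbar[v]])
        ok = s > 0
        if ok.sum() < 3:
            raise ValueError(f"voxel {v}: fewer than 3 usable powder points")
        X, y = X_full[ok], np.log(s[ok])
        beta = _wlls(X, y)
        resid = float(np.linalg.norm(y - X @ beta))
        msd = float(beta[1])
        clipped = msd < 0
        msd_for_k = max(msd, 0.0)
        msk = float(beta[2] / msd**2) if msd != 0 else float("nan")
        fits.append(
            MSDKIFit(
                msd=msd_for_k if clipped else msd,
                msk=msk,
                s0_fitted=float(np.exp(beta[0])),
                residual_norm=resid,
                clipped=clipped,
                negative_msk=bool(msk < 0),
            )
        )
    return fits


# 15 unique elements of a fully symmetric rank-4 tensor, with permutation counts
_W_UNIQUE: list[tuple[int, int, int, int]] = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
_W_MULT = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)


def _w_full_from_unique(w15: np.ndarray) -> np.ndarray:
    from itertools import permutations

    W = np.zeros((3, 3, 3, 3))
    for val, idx in zip(w15, _W_UNIQUE):
        for p in set(permutations(idx)):
            W[p] = val
    return W


def _quartic_monomials(n: np.ndarray) -> np.ndarray:
    """(N, 15) matrix of multiplicity-weighted quartic direction monomials."""
    cols = [
        _W_MULT[k] * n[:, i] * n[:, j] * n[:, l] * n[:, m]
        for k, (i, j, l, m) in enumerate(_W_UNIQUE)
    ]
    return np.stack(cols, axis=1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


_MK_DIRECTIONS = _fibonacci_sphere(1000)
_RK_ANGLES = np.linspace(0, np.pi, 180, endpoint=False)


def _apparent_kurtosis(D: np.ndarray, W: np.ndarray, md: float, dirs: np.ndarray) -> np.ndarray:
    d_app = np.einsum("ni,ij,nj->n", dirs, D, dirs)
    w_app = np.einsum("ni,nj,nk,nl,ijkl->n", dirs, dirs, dirs, dirs, W)
    return (md / d_app) ** 2 * w_app


def fit_dki(signals: SignalArray, scheme: AcquisitionScheme) -> list[DKIFit]:
    """22-parameter WLLS fit of the directional cumulant expansion.

    The linear unknowns are log S0, the six tensor elements, and the fifteen
    products MD²·W_ijkl (multiplicity-weighted in the design); W is recovered
    by dividing out MD² after the fit.  MK is the numerical average of the
    apparent kurtosis over a 1000-point spherical Fibonacci set, RK the
    average over 180 equally spaced directions in the plane perpendicular to
    the principal eigenvector, and AK the apparent kurtosis along it.
    """
    signals._check(scheme)
    bvals, bvecs = scheme.bvals, scheme.bvecs
    if scheme.shells.size < 2:
        raise ValueError("DKI needs at least two non-zero shells")
    X = np.column_stack(
        [
            np.ones_like(bvals),
            _dti_design(bvals, bvecs)[:, 1:],
            (bvals[:, None] ** 2 / 6.0) * _quartic_monomials(bvecs),
        ]
    )
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ValueError(f"ill-conditioned DKI design (condition number {cond:.3g})")
    fits: list[DKIFit] = []
    for v in range(signals.n_voxels):
        y = np.log(np.clip(signals.values[v], 1e-12, None))
        beta = _wlls(X, y)
        D = _tensor_from_coeffs(beta[1:7])
        md = float(np.trace(D) / 3.0)
        W = _w_full_from_unique(beta[7:] / md**2)
        evals, evecs = np.linalg.eigh(D)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        e1 = evecs[:, 0]
        # orthonormal basis of the radial plane
        e2, e3 = evecs[:, 1], evecs[:, 2]
        radial = (
            np.cos(_RK_ANGLES)[:, None] * e2[None, :]
            + np.sin(_RK_ANGLES)[:, None] * e3[None, :]
        )
        mk = float(_apparent_kurtosis(D, W, md, _MK_DIRECTIONS).mean())
        rk = float(_apparent_kurtosis(D, W, md, radial).mean())
        ak = float(_apparent_kurtosis(D, W, md, e1[None, :])[0])
        fits.append(
            DKIFit(
                D=D, W=W, md=md,
                rd=float(evals[1:].mean()), ad=float(evals[0]),
                mk=mk, rk=rk, ak=ak,
                fa=fa_from_eigenvalues(*evals),
                s0_fitted=float(np.exp(beta[0])),
            )
        )
    return fits


def roi_median_kurtosis(
    kurtosis_table: pd.DataFrame, roi_labels: np.ndarray
) -> pd.DataFrame:
    """Per-ROI median of voxelwise kurtosis metrics (robust to implausible fits).

    ``kurtosis_table`` holds one row per voxel (e.g. columns MK/RK/AK);
    ``roi_labels`` assigns each voxel to an ROI.  Empty ROIs do not appear.
    """
    labels = np.asarray(roi_labels)
    if len(labels) != len(kurtosis_table):
        raise ValueError("one label per voxel required")
    return kurtosis_table.groupby(labels).median()
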