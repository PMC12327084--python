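"""NODDI: three-compartment neurite orientation dispersion and density model.

The normalized signal is

    S(n, b)/S0 = (1 - Fiso) [Fia · Eia(n,b) + (1 - Fia) · Eea(n,b)]
                 + Fiso · exp(-b · Diso)

with an intra-neurite "stick" compartment dispersed by a Watson distribution
of concentration κ around a mean direction μ, an extra-neurite Gaussian
compartment whose tensor is the Watson-averaged axially symmetric tensor with
d∥ and d⊥ = d∥(1 - Fia) (tortuosity constraint), and free water with
Diso = 3 µm²/ms.  d∥ = 1.7 µm²/ms and Diso are fixed priors, never fitted.

The orientation dispersion index is ODI = 2·arctan(1/κ)/π: 0 for parallel
fibres (κ → ∞), 1 for a uniform orientation distribution (κ → 0).

Numerics: Watson integrals are evaluated by fixed-order spherical quadrature
(Gauss-Legendre in t = cos θ on [0, 1] exploiting antipodal symmetry, uniform
in azimuth), self-normalized so that the b = 0 attenuation is exactly 1.
Watson weights are computed as exp(κ(t² - 1)), so arbitrarily large κ cannot
overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.special import hyp1f1

from .core import AcquisitionScheme, ModelConstants, SignalArray

__all__ = [
    "NODDIFit",
    "WatsonODF",
    "watson_normalization",
    "watson_tau1",
    "odi_from_kappa",
    "kappa_from_odi",
    "noddi_forward",
    "fit_noddi",
    "apply_degenerate_convention",
    "NoddiGrid",
]

#: κ beyond which the parallel-stick closed form is used
KAPPA_PARALLEL = 1e5
#: default quadrature orders (polar x azimuthal)
DEFAULT_N_THETA = 60
DEFAULT_N_PHI = 60


def watson_normalization(kappa):
    """Watson normalization constant M(1/2, 3/2, κ) = ∫₀¹ exp(κ t²) dt.

    The Watson density on the sphere is exp(κ (μᵀu)²) / (4π M).  κ must be
    non-negative (dispersion only; the girdle regime κ < 0 is outside this
    model).  Large κ (> 700) switches to the asymptotic expansion
    e^κ/(2κ)·Σ (2m-1)!!/(2κ)^m to avoid overflow in the hypergeometric series.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("Watson concentration κ must be >= 0")
    out = np.empty_like(kappa)
    small = kappa <= 700
    out[small] = hyp1f1(0.5, 1.5, kappa[small])
    if (~small).any():
        k = kappa[~small]
        series = 1.0 + 1.0 / (2 * k) + 3.0 / (4 * k**2) + 15.0 / (8 * k**3)
        with np.errstate(over="ignore"):
            # beyond κ ≈ 709 the true value exceeds double range: +inf
            out[~small] = np.exp(k - np.log(2 * k) + np.log(series))
    return out if out.ndim else float(out)


def watson_tau1(kappa):
    """Mean squared projection τ₁ = ⟨(μᵀu)²⟩ under the Watson distribution.

    Equals ₁F₁(3/2,5/2,κ) / (3·₁F₁(1/2,3/2,κ)); 1/3 at κ=0 (uniform) and
    → 1 as κ → ∞ (parallel sticks).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("Watson concentration κ must be >= 0")
    out = np.empty_like(kappa)
    small = kappa <= 600
    out[small] = hyp1f1(1.5, 2.5, kappa[small]) / (3.0 * hyp1f1(0.5, 1.5, kappa[small]))
    if (~small).any():
        k = kappa[~small]
        out[~small] = 1.0 - 1.0 / k + 1.0 / (2 * k**2)  # d/dκ log M asymptotics
    return out if out.ndim else float(out)


def odi_from_kappa(kappa):
    """ODI = 2·arctan(1/κ)/π; κ = 0 maps to 1, κ = ∞ to 0."""
    kappa = np.asarray(kappa, dtype=float)
    with np.errstate(divide="ignore"):
        out = (2.0 / np.pi) * np.arctan(np.divide(1.0, kappa, where=kappa > 0,
                                                  out=np.full_like(kappa, np.inf)))
    out = np.where(kappa == 0, 1.0, out)
    out = np.where(np.isinf(kappa), 0.0, out)
    return out if out.ndim else float(out)


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa`: κ = 1/tan(π·ODI/2) on (0, 1]."""
    odi = np.asarray(odi, dtype=float)
    if np.any((odi < 0) | (odi > 1)):
        raise ValueError("ODI must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = np.where(odi == 0, np.inf, 1.0 / np.tan(np.pi * odi / 2.0))
    out = np.where(odi == 1.0, 0.0, out)
    return out if out.ndim else float(out)


@dataclass
class WatsonODF:
    """Axially symmetric Watson orientation distribution on the sphere."""

    mu: np.ndarray
    kappa: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float) / np.linalg.norm(self.mu)
        if self.kappa < 0:
            raise ValueError("κ must be >= 0")

    def pdf(self, u: np.ndarray) -> np.ndarray:
        """Density at unit vectors ``u`` (shape (..., 3)); integrates to 1."""
        t2 = (np.asarray(u) @ self.mu) ** 2
        return np.exp(self.kappa * (t2 - 1.0)) / (
            4 * np.pi * watson_normalization(self.kappa) * math.exp(-self.kappa)
        )


@lru_cache(maxsize=8)
def _quad_nodes(n_theta: int, n_phi: int):
    x, w = np.polynomial.legendre.leggauss(n_theta)
    t = 0.5 * (x + 1.0)          # cosθ on [0, 1] (antipodal symmetry)
    wt = 0.5 * w
    phi = np.arange(n_phi) * (2 * np.pi / n_phi)
    return t, wt, np.cos(phi)


def watson_stick_attenuation(
    bvals: np.ndarray,
    cos_psi: np.ndarray,
    kappa,
    d_par: float,
    n_theta: int = DEFAULT_N_THETA,
    n_phi: int = DEFAULT_N_PHI,
) -> np.ndarray:
    """Watson-dispersed stick attenuation Eia(n, b) = ∫ f(u) e^{-b d∥ (nᵀu)²} dΩ.

    ``cos_psi`` is |nᵀμ| per volume.  ``kappa`` may be scalar or a 1-D array;
    the result has shape (n_volumes,) or (n_kappa, n_volumes).  The quadrature
    is self-normalizing: b = 0 returns exactly 1.
    """
    bvals = np.asarray(bvals, dtype=float)
    c = np.clip(np.asarray(cos_psi, dtype=float), 0.0, 1.0)
    kap = np.atleast_1d(np.asarray(kappa, dtype=float))
    scalar_kappa = np.ndim(kappa) == 0
    t, wt, cphi = _quad_nodes(n_theta, n_phi)
    s = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    st = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    # (N, nt, nphi) projection nᵀu
    proj = c[:, None, None] * t[None, :, None] + (
        s[:, None] * st[None, :]
    )[:, :, None] * cphi[None, None, :]
    att = np.exp(-bvals[:, None, None] * d_par * proj**2).mean(axis=2)  # (N, nt)
    finite = np.minimum(kap, 1e8)
    # log-domain Watson weights, shifted by the per-κ maximum so that no
    # concentration can overflow or underflow the normalization
    ex = finite[:, None] * (t[None, :] ** 2)
    ex -= ex.max(axis=1, keepdims=True)
    ww = wt[None, :] * np.exp(ex)  # (K, nt)
    out = (ww @ att.T) / ww.sum(axis=1)[:, None]  # (K, N)
    parallel = ~np.isfinite(kap) | (kap > KAPPA_PARALLEL)
    if parallel.any():
        out[parallel] = np.exp(-bvals * d_par * c**2)[None, :]
    return out[0] if scalar_kappa else out


def _extra_axonal_attenuation(bvals, cos_psi, fia, kappa, d_par):
    """Eea(n,b) = exp(-b nᵀ⟨De⟩n) with the Watson-averaged tortuosity tensor.

    ⟨De⟩ = d⊥ I + (d∥ - d⊥) T, T = τ₁ μμᵀ + (1-τ₁)/2 (I - μμᵀ), so
    nᵀ⟨De⟩n is closed-form in cos ψ.
    """
    d_perp = d_par * (1.0 - fia)
    tau1 = 1.0 if (np.isinf(kappa) or kappa > KAPPA_PARALLEL) else watson_tau1(kappa)
    c2 = np.clip(cos_psi, 0.0, 1.0) ** 2
    proj = tau1 * c2 + 0.5 * (1.0 - tau1) * (1.0 - c2)
    return np.exp(-bvals * (d_perp + (d_par - d_perp) * proj))


def noddi_forward(
    scheme: AcquisitionScheme,
    fiso: float,
    fia: float,
    kappa: float,
    mu: np.ndarray,
    constants: ModelConstants = ModelConstants(),
    n_theta: int = DEFAULT_N_THETA,
    n_phi: int = DEFAULT_N_PHI,
) -> np.ndarray:
    """Predicted normalized signal S(n,b)/S0 for every volume of ``scheme``."""
    if not (0.0 <= fiso <= 1.0 and 0.0 <= fia <= 1.0):
        raise ValueError("volume fractions must lie in [0, 1]")
    if kappa <= 0 and not np.isinf(kappa):
        raise ValueError("Watson concentration κ must be > 0")
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    bvals = scheme.bvals
    cos_psi = np.abs(scheme.bvecs @ mu)
    eia = watson_stick_attenuation(bvals, cos_psi, kappa, constants.d_par, n_theta, n_phi)
    eea = _extra_axonal_attenuation(bvals, cos_psi, fia, kappa, constants.d_par)
    eiso = np.exp(-bvals * constants.d_iso)
    return (1.0 - fiso) * (fia * eia + (1.0 - fia) * eea) + fiso * eiso


@dataclass
class NODDIFit:
    """NODDI parameter estimates for one voxel."""

    fiso: float
    fia: float          # neurite density index (NDI)
    kappa: float
    odi: float
    mu: np.ndarray
    s0: float
    objective: float
    degenerate: bool = False
    converged: bool = True

    @property
    def ndi(self) -> float:
        return self.fia


@dataclass(frozen=True)
class NoddiGrid:
    """Coarse grid searched before derivative-based refinement."""

    fiso: tuple = tuple(np.round(np.arange(0.0, 0.91, 0.1), 2))
    fia: tuple = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))
    kappa: tuple = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


def _logit(p, lo=0.03):
    # initialization keeps fractions off the boundary so the logistic
    # transform retains a live gradient
    p = np.clip(p, lo, 1 - lo)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -15, 15)))


def fit_noddi(
    signals: SignalArray,
    scheme: AcquisitionScheme,
    grid: NoddiGrid | None = None,
    constants: ModelConstants = ModelConstants(),
    n_theta: int = DEFAULT_N_THETA,
    n_phi: int = DEFAULT_N_PHI,
    seed: int | None = None,
) -> list[NODDIFit]:
    """Grid-initialized nonlinear least-squares NODDI fit, one result per voxel.

    S0 is fixed to the b0 mean.  μ is initialized from the log-linear DTI
    principal eigenvector and held there during the grid search over
    (Fiso, Fia, κ); the best grid point seeds a bounded refinement over
    (Fiso, Fia, κ, μ) in transformed coordinates (logistic fractions, log κ,
    spherical angles) minimizing the sum of squared signal residuals.
    d∥ and Diso stay at their fixed priors throughout.  Deterministic given
    the grid; ``seed`` is accepted for interface uniformity (the fit itself
    draws no random numbers).
    """
    from scipy.optimize import least_squares

    from .tensors import loglinear_dti

    if grid is None:
        grid = NoddiGrid()
    if scheme.shells.size < 1:
        raise ValueError("scheme has no diffusion-weighted shell; refusing to fit")
    signals._check(scheme)
    tensors0, _ = loglinear_dti(signals, scheme)
    bvals = scheme.bvals
    eiso = np.exp(-bvals * constants.d_iso)
    fiso_g = np.asarray(grid.fiso)
    fia_g = np.asarray(grid.fia)
    kap_g = np.asarray(grid.kappa)

    fits: list[NODDIFit] = []
    for v in range(signals.n_voxels):
        s0 = float(signals.values[v, scheme.b0_mask].mean())
        if s0 <= 0:
            fits.append(NODDIFit(np.nan, np.nan, np.nan, np.nan, np.zeros(3), s0,
                                 np.inf, degenerate=True, converged=False))
            continue
        y = signals.values[v] / s0
        evals, evecs = np.linalg.eigh(tensors0[v])
        mu0 = evecs[:, np.argmax(evals)]

        cos_psi = np.abs(scheme.bvecs @ mu0)
        eia_g = watson_stick_attenuation(bvals, cos_psi, kap_g, constants.d_par,
                                         n_theta, n_phi)                 # (K, N)
        d_perp = constants.d_par * (1.0 - fia_g)                          # (A,)
        tau1 = watson_tau1(kap_g)                                         # (K,)
        c2 = np.clip(cos_psi, 0, 1) ** 2
        proj = tau1[:, None] * c2[None, :] + 0.5 * (1 - tau1)[:, None] * (1 - c2)[None, :]
        eea_g = np.exp(-bvals[None, None, :] * (d_perp[:, None, None]
                       + (constants.d_par - d_perp)[:, None, None] * proj[None, :, :]))  # (A, K, N)
        aniso = (fia_g[:, None, None] * eia_g[None, :, :]
                 + (1 - fia_g)[:, None, None] * eea_g)                    # (A, K, N)
        pred = ((1 - fiso_g)[:, None, None, None] * aniso[None, :, :, :]
                + fiso_g[:, None, None, None] * eiso[None, None, None, :])  # (F, A, K, N)
        sse = ((pred - y) ** 2).sum(axis=-1)
        f_i, a_i, k_i = np.unravel_index(np.argmin(sse), sse.shape)
        best = (float(fiso_g[f_i]), float(fia_g[a_i]), float(kap_g[k_i]))
        best_obj = float(sse[f_i, a_i, k_i])

        theta0 = math.acos(np.clip(mu0[2], -1, 1))
        phi0 = math.atan2(mu0[1], mu0[0])

        def residuals(x):
            fiso, fia = _expit(x[0]), _expit(x[1])
            kappa = math.exp(np.clip(x[2], math.log(0.01), math.log(128.0)))
            mu = np.array([math.sin(x[3]) * math.cos(x[4]),
                           math.sin(x[3]) * math.sin(x[4]),
                           math.cos(x[3])])
            return noddi_forward(scheme, fiso, fia, kappa, mu, constants,
                                 n_theta, n_phi) - y

        # two starts: the best grid point and a fixed mid-range fallback that
        # guards against the Fiso/Fia trade-off degeneracy near the boundary
        starts = [best, (0.15, 0.55, 3.0)]
        res = None
        for s in starts:
            x0 = np.array([_logit(s[0]), _logit(s[1]),
                           math.log(np.clip(s[2], 0.01, 128.0)), theta0, phi0])
            r = least_squares(residuals, x0, method="lm", xtol=1e-10, ftol=1e-10,
                              max_nfev=400)
            if res is None or np.sum(r.fun**2) < np.sum(res.fun**2):
                res = r
        obj = float(np.sum(res.fun**2))
        converged = bool(res.success) and obj <= best_obj + 1e-12
        if obj <= best_obj:
            fiso = float(_expit(res.x[0]))
            fia = float(_expit(res.x[1]))
            kappa = float(np.clip(math.exp(res.x[2]), 0.01, 128.0))
            mu = np.array([math.sin(res.x[3]) * math.cos(res.x[4]),
                           math.sin(res.x[3]) * math.sin(res.x[4]),
                           math.cos(res.x[3])])
        else:  # keep the grid point, flag non-convergence
            fiso, fia, kappa, mu, obj = (*best, mu0, best_obj)
            converged = False
        if mu[2] < 0:
            mu = -mu  # antipodal convention: upper hemisphere
        fits.append(NODDIFit(fiso=fiso, fia=fia, kappa=kappa,
                             odi=odi_from_kappa(kappa), mu=mu, s0=s0,
                             objective=obj, converged=converged))
    return fits


def apply_degenerate_convention(fit: NODDIFit, cutoff: float = 0.9) -> NODDIFit:
    """Convention for free-water-dominated voxels: Fiso > cutoff (strict) is
    unidentifiable in (NDI, ODI), so NDI is set to 0 and ODI to 1, flagged.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    if fit.fiso > cutoff:
        return replace(fit, fia=0.0, odi=1.0, kappa=0.0, degenerate=True)
    return fit
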