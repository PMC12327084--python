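"""Mean-signal metrics are invariant to fibre configuration; FA is not.

Two voxels built from the same tissue compartments — one single fibre, one
90° crossing — give the same powder-averaged MSD/MSK (here on a dense
spherical-quadrature direction set), while the DTI FA collapses in the
crossing voxel.  A second sweep shows FA falling as orientation dispersion
rises at fixed density.
"""

import numpy as np

from dmriage import SignalArray, fit_dti, fit_msdki, powder_average
from dmriage.noddi import noddi_forward
from dmriage.synthetic import make_dense_scheme, make_scheme

dense, weights = make_dense_scheme(n_theta=32, n_phi=64)
fia, d_par = 0.55, 1.7
d_perp = d_par * (1 - fia)


def compartments(scheme, axes_weights):
    sig = np.zeros(scheme.n_volumes)
    for axis, w in axes_weights:
        c2 = (scheme.bvecs @ np.asarray(axis, float)) ** 2
        sig += w * (fia * np.exp(-scheme.bvals * d_par * c2)
                    + (1 - fia) * np.exp(-scheme.bvals
                                         * (d_perp + (d_par - d_perp) * c2)))
    return sig


for name, axes in [("single fibre ", [([0, 0, 1.0], 1.0)]),
                   ("90 deg cross ", [([0, 0, 1.0], 0.5), ([1.0, 0, 0], 0.5)])]:
    sig = compartments(dense, axes)
    fit = fit_msdki(powder_average(SignalArray(sig[None, :]), dense,
                                   weights=weights))[0]
    camcan = make_scheme()
    fa = fit_dti(SignalArray(compartments(camcan, axes)[None, :]), camcan)[0].fa
    print(f"{name}: MSD={fit.msd:.6f}  MSK={fit.msk:.6f}  FA={fa:.3f}")

print()
print("FA versus orientation dispersion at fixed NDI=0.6, Fiso=0.05:")
camcan = make_scheme()
for kappa, odi in [(64.0, 0.01), (16.0, 0.04), (4.0, 0.16), (1.0, 0.50)]:
    sig = noddi_forward(camcan, 0.05, 0.6, kappa, [0, 0, 1.0])
    fa = fit_dti(SignalArray(sig[None, :]), camcan)[0].fa
    print(f"  ODI~{odi:.2f}: FA={fa:.3f}")
print()
print("Identical MSD/MSK across configurations, diverging FA: directional")
print("metrics confound microstructure with fibre geometry.")
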