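"""Leaf position-penumbra curves for the optimal leaf ends of each family.

A single-focused MLC translates its leaves, so the rounded tip meets the
diverging beam at a position-dependent angle and the penumbra varies along
the stroke.  The sweep statistics (mean, sample standard deviation) are the
two design objectives.
"""

import numpy as np

from mlcpen import (MachineScene, SourceDistribution, TSTParams, leaf_end,
                    position_sweep, sample_positions)

scene = MachineScene(sad=100, scd=46, fs=40, lh=8, rho=19.3, mu_rho=0.05)
src = SourceDistribution(fwhms=(0.2,))
params = TSTParams(e=0.152, l=1.174)
positions = sample_positions(-20.0, 20.0, 17)  # 2.5 cm steps at isocentre

optima = {
    "circular R=16.213 d=-0.732": leaf_end("circular", 8.0, R=16.213, d=-0.732),
    "elliptical b=0.728": leaf_end("elliptical", 8.0, b=0.728),
    "bezier P1=(-1.594,1.077) P2=(0.814,0.748)":
        leaf_end("bezier", 8.0, control=[(-1.594, 1.077), (0.814, 0.748)]),
}

for name, spec in optima.items():
    W = position_sweep(spec, positions, params, scene, src)
    print(f"{name:45s} mean = {W.mean():.4f} cm  sd = {W.std(ddof=1):.5f} cm")
    # The Bezier optimum trades a slightly larger mean for a near-flat curve
    # (sd below a micrometre-scale fraction of the mean).

W = position_sweep(leaf_end("circular", 8.0, R=25.0, d=0.0), positions,
                   params, scene, src)
print(f"\nlarge radius R=25: W(-20) = {W[0]:.3f}, min = {W.min():.3f}, "
      f"W(+20) = {W[-1]:.3f} cm  (bowl shape: beam clips the leaf edges)")
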