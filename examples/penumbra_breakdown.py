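"""Evaluate one tangent/secant penumbra and show its geometric decomposition.

The 80% point comes from a tangent line grazing the leaf tip from the source
point that leaves 80% of the focal spot visible; the 20% point from a secant
ray whose chord through the tip equals the effective path length.
"""

from mlcpen import (MachineScene, SourceDistribution, TSTParams, leaf_end,
                    tst_penumbra)

scene = MachineScene(sad=100, scd=46, fs=40, lh=8, rho=19.3, mu_rho=0.05)
src = SourceDistribution(fwhms=(0.2,))
params = TSTParams(e=0.152, l=1.174)
spec = leaf_end("circular", 8.0, R=16.213, d=-0.732)

bd = tst_penumbra(spec, T=0.0, params=params, scene=scene, src=src)
print(f"leaf position T = {bd.T:g} cm (lateral leaf shift tau = {bd.tau:.3f} cm)")
print(f"P80 = {bd.p80:+.4f} cm   (tangent from E = {bd.E[1]:+.4f} cm, "
      f"touching the tip at depth {bd.D[0]:.2f} cm)")
print(f"P20 = {bd.p20:+.4f} cm   (secant from C = {bd.C_src[1]:+.4f} cm, "
      f"chord {params.l} cm through the tip)")
print(f"penumbra width W = P80 - P20 = {bd.W:.4f} cm")
# W is the distance on the isocentre plane over which the in-air beam
# intensity falls from 80% to 20% of the open-field value.
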