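"""Compare an optimised circular arc with the actual piecewise leaf end of a
5.65 cm leaf (central 8 cm arc blended into straight 11.3-degree bevels).

Each leaf's absolute lateral position is a machine calibration, so the
shapes are aligned by the minimax vertical shift before measuring the
maximum lateral deviation.
"""

from mlcpen import leaf_end, max_lateral_deviation, varian_piecewise_end

circle = leaf_end("circular", 5.65, R=12.354, d=-0.125)
actual = varian_piecewise_end(R=8.0, alpha_l=11.3, lh=5.65)

dev = max_lateral_deviation(circle, actual, align="minimax")
print(f"blend points of the piecewise end: x = +-{actual.xb:.3f} cm")
print(f"max lateral deviation over the leaf height: {dev:.4f} cm")
# A deviation well below a millimetre means the optimised arc is a close
# stand-in for the manufactured piecewise tip.
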