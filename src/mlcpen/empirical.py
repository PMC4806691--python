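"""Closed-form empirical optimal radius for a circular-arc leaf end.

The chord-intersection empirical rule expresses the optimal radius as a
function of the linear attenuation coefficient, the source-axis distance,
the maximum field size and the leaf height.  It serves as a sanity
comparison for the model-based optimum (which tends to come out slightly
smaller).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EmpiricalInputs", "empirical_radius", "empirical_terms"]


@dataclass(frozen=True)
class EmpiricalInputs:
    mu_a: float  # linear attenuation coefficient (1/cm)
    sad: float   # source-to-axis distance (cm)
    fs: float    # maximum square field side (cm)
    lh: float    # leaf height (cm)

    def __post_init__(self):
        if min(self.mu_a, self.sad, self.fs, self.lh) <= 0:
            raise ValueError("all empirical inputs must be positive")


def empirical_terms(inp: EmpiricalInputs):
    """The four auxiliary terms of the empirical radius formula."""
    a1 = np.log(0.2) / inp.mu_a
    a2 = inp.sad / inp.fs
    a3 = np.sqrt(4.0 * inp.sad**2 + inp.fs**2) / inp.sad
    a4 = inp.lh
    return a1, a2, a3, a4


def empirical_radius(inp: EmpiricalInputs) -> float:
    """Empirical optimal circular-arc radius (cm)."""
    a1, a2, a3, a4 = empirical_terms(inp)
    radicand = (a1**2 + 4 * a1**2 * a2**2 + 4 * a1 * a2**2 * a3 * a4
                + a4**2 + 4 * a2**2 * a4**2)
    if radicand < 0:
        raise ValueError("parameter regime outside the formula's validity "
                         "(negative radicand)")
    return float(0.5 * np.sqrt(radicand))
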