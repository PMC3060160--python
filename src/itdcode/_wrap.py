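"""Phase wrapping helpers shared across modules.

All phases in this package are expressed in cycles (1 cycle = 2*pi rad =
one stimulus period).  The canonical wrapped interval is the half-open
interval (-0.5, 0.5], matching the convention that an antiphasic cell has
characteristic phase +0.5, not -0.5.
"""

from __future__ import annotations

import numpy as np


def wrap_half(phase_cycles):
    """Wrap a phase (cycles) to the interval (-0.5, 0.5].

    Works on scalars and arrays.  The right edge is kept: ``wrap_half(0.5)
    == 0.5`` and ``wrap_half(-0.5) == 0.5``.
    """
    return 0.5 - np.mod(0.5 - np.asarray(phase_cycles), 1.0)


def circ_mean(phase_cycles, weights=None) -> float:
    """Circular mean of phases given in cycles, wrapped to (-0.5, 0.5]."""
    ph = np.asarray(phase_cycles, dtype=float)
    z = np.exp(2j * np.pi * ph)
    m = np.average(z, weights=weights)
    return float(wrap_half(np.angle(m) / (2 * np.pi)))


def circ_dist(a, b):
    """Signed circular distance a - b in cycles, wrapped to (-0.5, 0.5]."""
    return wrap_half(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def resultant_length(phase_cycles, weights=None) -> float:
    """Mean resultant length of phases (cycles); 1 for identical phases."""
    ph = np.asarray(phase_cycles, dtype=float)
    z = np.exp(2j * np.pi * ph)
    return float(np.abs(np.average(z, weights=weights)))
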