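"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: the fork
simulator works per cell on the steady-state age distribution, and the
bisector oracle tests rectangle/line intersection geometrically.
"""

import numpy as np


def fork_population_dosage(rel_distance, c_over_tau, n_cells, seed):
    """Monte-Carlo mean copy number of loci by per-cell fork positions.

    In a steady-state exponential culture the cell-age density (in units
    of the doubling time) is ``2 ln2 * 2**(-a)`` on [0, 1).  A replicon
    whose forks take a fraction ``c_over_tau`` (<= 1) of the cycle and
    finish at division initiates at age ``1 - c_over_tau``; a locus at
    relative arm distance ``d`` is replicated at age
    ``1 - c_over_tau*(1-d)``, after which the cell carries 2 copies.
    Returns the mean copies per cell for each entry of ``rel_distance``.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n_cells)
    ages = -np.log2(1.0 - u / 2.0)  # inverse CDF of 2ln2*2^-a on [0,1)
    d = np.asarray(rel_distance, dtype=float)
    thresholds = 1.0 - c_over_tau * (1.0 - d)
    return (1.0 + (ages[:, None] >= thresholds[None, :])).mean(axis=0)


def rectangle_crosses_bisector(x, y, ex, ey):
    """Does the axis-aligned rectangle [x-ex, x+ex] x [y-ey, y+ey]
    intersect the line y = x?  Decided from the sign of (x - y) at the
    corners: the line passes through the rectangle iff the corner
    differences are not all strictly of one sign."""
    corners = [
        (x - ex) - (y - ey),
        (x - ex) - (y + ey),
        (x + ex) - (y - ey),
        (x + ex) - (y + ey),
    ]
    return not (all(c > 0 for c in corners) or all(c < 0 for c in corners))
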