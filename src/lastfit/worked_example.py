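"""Published two-generation worked example of the four-parent crossover.

A 16-gene weight-optimisation trace (control points of one quintic patch on
a ~27 mm surface): for each of two consecutive generations, the four parent
vectors, the six children produced by the crossover operators, and the
per-vector fitness.  The underlying surface data are not published, so the
fitness values validate only the *selection* logic; the parent/child columns
validate the crossover algebra.  All child columns of each generation share
a single spread factor beta, which :func:`back_solve_spread_factor` recovers
from the printed values.

Values are printed to 4 decimals; reproduction tolerances must allow
~2e-3 mm of input-rounding noise.
"""

from __future__ import annotations

import numpy as np

from .ga import select_parents

#: row labels: interior control-point weights W[1..4, 1..4] of one patch
GENE_LABELS = [f"P{i},{j}" for i in range(1, 5) for j in range(1, 5)]

# generation 1: columns P1 P2 P3 P4 | C1 C2 C3 C4 C5 C6
_GEN1 = np.array([
    [27.6631, 27.6942, 27.8012, 27.3941, 27.6860, 27.6712, 27.3150, 27.6943, 27.5010, 27.7320],
    [27.2626, 27.0576, 28.1047, 27.2793, 27.2087, 27.1114, 27.0277, 27.8881, 27.4960, 27.7907],
    [26.5554, 27.1792, 28.3741, 28.2896, 27.0154, 26.7191, 26.5410, 28.3519, 28.3118, 28.4720],
    [26.4820, 26.8381, 28.4118, 28.0240, 26.7446, 26.5754, 26.2859, 28.3100, 28.1258, 28.5242],
    [27.5308, 27.7513, 26.9891, 26.6823, 27.6935, 27.5887, 27.0835, 26.9086, 26.7628, 27.6064],
    [27.3844, 27.3601, 27.5913, 26.8560, 27.3780, 27.3664, 26.9126, 27.3983, 27.0490, 27.8097],
    [28.3583, 27.3628, 27.5642, 27.7009, 28.0970, 27.6241, 27.2106, 27.6650, 27.6001, 28.2015],
    [27.6445, 27.2725, 28.8380, 26.6733, 27.5469, 27.3702, 26.6198, 28.2698, 27.2415, 27.9831],
    [27.4728, 26.6841, 26.3958, 26.5373, 27.2658, 26.8911, 26.7648, 26.5002, 26.4330, 27.6988],
    [27.7614, 26.0223, 28.3057, 28.2128, 27.3049, 26.4788, 26.8248, 28.2813, 28.2372, 28.4999],
    [27.6942, 27.9179, 27.3464, 28.0121, 27.8592, 27.7529, 26.6368, 27.8373, 27.5211, 28.5025],
    [27.1917, 29.3360, 29.0766, 27.5495, 28.7732, 27.7545, 26.1338, 28.6757, 27.9503, 28.5235],
    [26.6644, 25.4581, 28.4788, 25.7886, 26.3478, 25.7748, 25.9372, 27.7727, 26.4947, 27.3046],
    [26.7604, 25.5230, 27.9312, 25.8832, 26.4356, 25.8478, 25.9693, 27.3936, 26.4207, 27.2654],
    [27.2411, 28.5583, 28.0305, 26.1894, 28.2126, 27.5869, 26.0801, 27.5473, 26.6727, 27.4968],
    [28.2807, 25.0608, 24.5530, 27.1651, 27.4355, 25.9059, 26.3211, 26.4795, 25.2386, 28.3272],
])

GEN1_PARENTS = _GEN1[:, :4].copy()
GEN1_CHILDREN = _GEN1[:, 4:].copy()
#: fitness of (P1..P4, C1..C6) in generation 1
GEN1_FITNESS = np.array(
    [1.6517, 1.6546, 1.8663, 1.7220, 1.6823, 1.6240, 1.5301, 1.8333, 1.7542, 1.8857]
)

# generation 2: columns P1 P2 P3 P4 | C1..C6 | optimal control points
_GEN2 = np.array([
    [27.6631, 27.3150, 27.3941, 27.4582, 27.5717, 27.4064, 27.1151, 27.4414, 27.4110, 27.7624, 26.7601],
    [27.2626, 27.0277, 27.2793, 27.8708, 27.2009, 27.0893, 26.9217, 27.7156, 27.4346, 28.0716, 26.4022],
    [26.5554, 26.5410, 28.2896, 27.2305, 26.5516, 26.5448, 26.3110, 28.0116, 27.5085, 27.9689, 26.1003],
    [26.4820, 26.2859, 28.0240, 26.1476, 26.4305, 26.3374, 26.1759, 27.5315, 26.6401, 27.6328, 25.6511],
    [27.5308, 27.0835, 26.6823, 28.0726, 27.4134, 27.2009, 26.8352, 27.7077, 27.0472, 28.2668, 26.4028],
    [27.3844, 26.9126, 26.8560, 27.6333, 27.2605, 27.0365, 26.7126, 27.4293, 27.0600, 28.1789, 26.1635],
    [28.3583, 27.2106, 27.7009, 27.8151, 28.0570, 27.5118, 26.7106, 27.7851, 27.7309, 28.2557, 25.8065],
    [27.6445, 26.6198, 26.6733, 25.9186, 27.3755, 26.8888, 26.3198, 26.4752, 26.1167, 27.6246, 25.2117],
    [27.4728, 26.7648, 26.5373, 27.1942, 27.2870, 26.9507, 26.5648, 27.0218, 26.7097, 28.0109, 25.8140],
    [27.7614, 26.8248, 28.2128, 27.9188, 27.5155, 27.0706, 26.6218, 28.1357, 27.9960, 28.3602, 25.5962],
    [27.6942, 26.6368, 28.0121, 27.3629, 27.4166, 26.9143, 26.0318, 27.8417, 27.5333, 28.1941, 25.3564],
    [27.1917, 26.1338, 27.5495, 27.9348, 26.9140, 26.4115, 25.9133, 27.8336, 27.6506, 28.7065, 24.6168],
    [26.6644, 25.9372, 25.7886, 26.5850, 26.4735, 26.1281, 25.7371, 26.3759, 25.9977, 27.6829, 24.8471],
    [26.7604, 25.9693, 25.8832, 26.7065, 26.5528, 26.1770, 25.8613, 26.4904, 26.0993, 27.6565, 24.7543],
    [27.2411, 26.0801, 26.1894, 27.1748, 26.9364, 26.3849, 25.8801, 26.9162, 26.4481, 27.9649, 24.6025],
    [28.2807, 26.3211, 27.1651, 24.5809, 27.7663, 26.8354, 26.2221, 26.4868, 25.2592, 27.0996, 23.8512],
])

GEN2_PARENTS = _GEN2[:, :4].copy()
GEN2_CHILDREN = _GEN2[:, 4:10].copy()
#: converged control points reported alongside generation 2
GEN2_OPTIMAL_CONTROL_POINTS = _GEN2[:, 10].copy()
#: fitness of (P1..P4, C1..C6, optimum) in generation 2
GEN2_FITNESS = np.array(
    [1.6517, 1.5301, 1.7220, 1.6498, 1.6194, 1.5616, 1.0085, 1.7388, 1.6299, 1.8490, 0.000461]
)


def inside_child_cells(parents: np.ndarray, children: np.ndarray):
    """(parent_a, parent_b, child, sign) arrays for every inside-child cell.

    Inside children are C1/C2 of the pair (P1, P2) and C4/C5 of (P4, P3);
    sign +1 marks the high-spread child of the pair.
    """
    p1, p2, p3, p4 = (parents[:, k] for k in range(4))
    c1, c2, c4, c5 = children[:, 0], children[:, 1], children[:, 3], children[:, 4]
    pa = np.concatenate([p1, p1, p4, p4])
    pb = np.concatenate([p2, p2, p3, p3])
    c = np.concatenate([c1, c2, c4, c5])
    sign = np.concatenate([np.ones_like(p1), -np.ones_like(p1)] * 2)
    return pa, pb, c, sign


def back_solve_spread_factor(
    parents: np.ndarray, children: np.ndarray, row: int | None = None
) -> float:
    """Recover the shared beta from printed inside-child cells.

    With ``row`` given, inverts the single (P1, P2, C1) triple of that row.
    Otherwise solves the gap-weighted least-squares problem over all 64
    inside-child cells — rows with a small parent gap amplify 4-decimal
    rounding into the per-cell estimate, so the table-wide solve is the
    reliable one (it reproduces every cell to ~1e-4).
    """
    if row is not None:
        p1, p2 = parents[row, 0], parents[row, 1]
        return abs(2.0 * children[row, 0] - (p1 + p2)) / abs(p1 - p2)
    pa, pb, c, sign = inside_child_cells(parents, children)
    gap = np.abs(pa - pb)
    beta_cell = sign * (2.0 * c - (pa + pb)) / gap
    return float(np.sum(beta_cell * gap**2) / np.sum(gap**2))


def predicted_inside_children(parents: np.ndarray, beta: float) -> np.ndarray:
    """All 64 inside-child cells (C1 | C2 | C4 | C5 stacked) for a given beta."""
    p1, p2, p3, p4 = (parents[:, k] for k in range(4))
    pa = np.concatenate([p1, p1, p4, p4])
    pb = np.concatenate([p2, p2, p3, p3])
    sign = np.concatenate([np.ones_like(p1), -np.ones_like(p1)] * 2)
    return 0.5 * ((pa + pb) + sign * beta * np.abs(pa - pb))


def selection_trace(fitness_row: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Apply the pool-selection rule to a printed 10-value fitness row.

    Returns the chosen column labels (in P1', P2', P3', P4' order) and their
    fitness values.
    """
    fitness_row = np.asarray(fitness_row, dtype=float)
    dummy = np.zeros((1,))
    parents = np.tile(dummy, (4, 1))
    children = np.tile(dummy, (6, 1))
    _, fits, labels = select_parents(parents, children, fitness_row[:4], fitness_row[4:])
    return labels, fits
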