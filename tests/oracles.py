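"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: superposition is
solved by a dense rotation-space search, isoform mapping by an explicit
letter-by-letter alignment, and conservation counts by brute-force column
scans.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_rmsd(P: np.ndarray, Q: np.ndarray, grid: float = np.pi / 8,
                     refine: int = 20) -> float:
    """Minimum RMSD over proper rotations by grid search + simplex refinement."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1)))

    candidates = []
    for a in np.arange(0, 2 * np.pi, grid):
        for b in np.arange(0, np.pi + 1e-9, grid):
            for c in np.arange(0, 2 * np.pi, grid):
                rv = Rotation.from_euler("zyz", [a, b, c]).as_rotvec()
                candidates.append((cost(rv), rv))
    candidates.sort(key=lambda x: x[0])
    best = np.inf
    for _, rv in candidates[:refine]:
        res = minimize(cost, rv, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-14, maxiter=20000))
        best = min(best, float(res.fun))
    return best


def mapping_alignment_columns(mapping) -> list[tuple[int | None, int | None]]:
    """Explicit alignment columns (a_pos, b_pos) implied by a mapping's edits."""
    cols: list[tuple[int | None, int | None]] = []
    a, b = 1, 1
    for e in mapping.edits:
        while a < e.start_in_A:
            cols.append((a, b))
            a += 1
            b += 1
        if e.kind == "insertion":
            for _ in range(e.length):
                cols.append((None, b))
                b += 1
        else:
            for _ in range(e.length):
                cols.append((a, None))
                a += 1
    while a <= mapping.length_A:
        cols.append((a, b))
        a += 1
        b += 1
    return cols


def random_valid_mapping(rng: np.random.Generator):
    """A random isoform mapping with non-overlapping edits, plus its lengths."""
    from isodyn.isoforms import IsoformEdit, IsoformMapping

    length_a = int(rng.integers(30, 120))
    n_edits = int(rng.integers(0, 4))
    edits = []
    cursor = 1
    for _ in range(n_edits):
        gap = int(rng.integers(2, 15))
        start = cursor + gap
        if start > length_a:
            break
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        max_len = 8 if kind == "insertion" else min(8, length_a - start + 1)
        if max_len < 1:
            break
        length = int(rng.integers(1, max_len + 1))
        edits.append(IsoformEdit(kind, start, length))
        cursor = start + (length - 1 if kind == "deletion" else 0)
    net = sum(e.length if e.kind == "insertion" else -e.length for e in edits)
    return IsoformMapping("A", "B", length_a, length_a + net, edits)
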