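"""Independent brute-force oracles shared by the test modules."""

from collections import deque

import numpy as np


def flood_fill_components(mask, connectivity=26):
    """Breadth-first flood-fill 3D connected components.

    Returns a set of frozensets of voxel tuples; deliberately independent of
    the scipy-based implementation it checks.
    """
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            p = q.popleft()
            comp.append(p)
            for d in offsets:
                n = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if all(0 <= n[a] < mask.shape[a] for a in range(3)):
                    if mask[n] and not seen[n]:
                        seen[n] = True
                        q.append(n)
        comps.append(frozenset(comp))
    return set(comps)
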