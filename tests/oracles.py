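"""Independent brute-force oracles used by the test suite only."""

import numpy as np


def flood_fill_components(plane: np.ndarray, connectivity: int = 8):
    """Connected components of a 2D binary plane via BFS flood fill."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(plane, dtype=bool)
    comps = []
    h, w = plane.shape
    for i in range(h):
        for j in range(w):
            if plane[i, j] and not seen[i, j]:
                queue = [(i, j)]
                seen[i, j] = True
                comp = []
                while queue:
                    y, x = queue.pop()
                    comp.append((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < h and 0 <= nx < w
                            and plane[ny, nx] and not seen[ny, nx]
                        ):
                            seen[ny, nx] = True
                            queue.append((ny, nx))
                comps.append(comp)
    return comps


def size_filter(mask3d: np.ndarray, min_size: int, connectivity: int = 8) -> np.ndarray:
    """Per-B-scan small-component removal via the flood-fill oracle."""
    out = np.zeros_like(mask3d)
    for b in range(mask3d.shape[0]):
        for comp in flood_fill_components(mask3d[b], connectivity):
            if len(comp) >= min_size:
                for y, x in comp:
                    out[b, y, x] = True
    return out
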