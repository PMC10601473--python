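import numpy as np


def brute_force_minimax(values, mask, start, goal):
    """Minimum over all 4-neighbor paths of the path maximum, by exhaustive
    depth-first enumeration of simple paths (oracle for the union-find
    saddle finder; only feasible on small grids)."""
    nr, nt = values.shape
    best = [np.inf]

    def neighbors(c):
        r, t = c
        for dr, dt in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, tt = r + dr, t + dt
            if 0 <= rr < nr and 0 <= tt < nt and mask[rr, tt]:
                yield (rr, tt)

    def dfs(cell, seen, cur_max):
        cur_max = max(cur_max, values[cell])
        if cur_max >= best[0]:
            return
        if cell == goal:
            best[0] = cur_max
            return
        for nb in neighbors(cell):
            if nb not in seen:
                dfs(nb, seen | {nb}, cur_max)

    dfs(start, {start}, -np.inf)
    return best[0]
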