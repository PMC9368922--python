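"""Numba kernel for the constrained random walk on the 20 nm cubic lattice.

The chain alternates 60-monomer loops and 60-monomer linkers.  A loop is
generated brute-force: fresh 59-step candidates are drawn until the last loop
monomer lands on a lattice neighbor of the loop start.  Every proposed step is
rejected and resampled if it would leave the nucleus, or the chromosome domain
when the walk is domain-constrained.
"""

import numpy as np
from numba import njit

# status codes returned by walk_kernel
WALK_OK = 0
WALK_STUCK = 1          # no admissible step after step_budget resamples
WALK_LOOP_BUDGET = 2    # loop failed to close within loop_budget candidates

_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int32,
)


@njit(cache=True)
def _admissible(x, y, z, nuc_inv2, dom_c, dom_inv2, constrain):
    if x * x * nuc_inv2[0] + y * y * nuc_inv2[1] + z * z * nuc_inv2[2] > 1.0:
        return False
    if constrain:
        dx = x - dom_c[0]
        dy = y - dom_c[1]
        dz = z - dom_c[2]
        if dx * dx * dom_inv2[0] + dy * dy * dom_inv2[1] + dz * dz * dom_inv2[2] > 1.0:
            return False
    return True


@njit(cache=True)
def _try_step(x, y, z, steps, nuc_inv2, dom_c, dom_inv2, constrain, step_budget):
    """Sample lattice directions until one stays inside; (-1,...) if stuck."""
    for _ in range(step_budget):
        d = np.random.randint(0, 6)
        nx = x + steps[d, 0]
        ny = y + steps[d, 1]
        nz = z + steps[d, 2]
        if _admissible(nx, ny, nz, nuc_inv2, dom_c, dom_inv2, constrain):
            return nx, ny, nz, 0
    return x, y, z, 1


@njit(cache=True)
def walk_kernel(pos, nuc_inv2, dom_c, dom_inv2, constrain,
                loop_len, linker_len, loop_budget, step_budget, seed):
    """Fill ``pos`` (n x 3 int32; row 0 pre-set to the start) in place.

    Returns (status, failed_monomer_index).
    """
    np.random.seed(seed)
    steps = _STEPS
    n = pos.shape[0]
    period = loop_len + linker_len
    j = 1
    while j < n:
        o = j % period
        if o == 0 or o >= loop_len:
            # linker monomer, or the first monomer of a new loop: ordinary step
            x, y, z, bad = _try_step(pos[j - 1, 0], pos[j - 1, 1], pos[j - 1, 2],
                                     steps, nuc_inv2, dom_c, dom_inv2,
                                     constrain, step_budget)
            if bad:
                return WALK_STUCK, j
            pos[j, 0] = x
            pos[j, 1] = y
            pos[j, 2] = z
            j += 1
        else:
            # o == 1: generate the body of the loop anchored at pos[j-1]
            anchor = j - 1
            k = loop_len - 1  # monomers anchor+1 .. anchor+k
            if anchor + k > n - 1:
                k = n - 1 - anchor  # truncated tail: plain walk, no closure
            ax = pos[anchor, 0]
            ay = pos[anchor, 1]
            az = pos[anchor, 2]
            if k < loop_len - 1:
                for m in range(1, k + 1):
                    x, y, z, bad = _try_step(
                        pos[anchor + m - 1, 0], pos[anchor + m - 1, 1],
                        pos[anchor + m - 1, 2], steps, nuc_inv2, dom_c,
                        dom_inv2, constrain, step_budget)
                    if bad:
                        return WALK_STUCK, anchor + m
                    pos[anchor + m, 0] = x
                    pos[anchor + m, 1] = y
                    pos[anchor + m, 2] = z
            else:
                closed = False
                for _ in range(loop_budget):
                    x, y, z = ax, ay, az
                    ok = True
                    for m in range(1, k + 1):
                        x, y, z, bad = _try_step(x, y, z, steps, nuc_inv2,
                                                 dom_c, dom_inv2, constrain,
                                                 step_budget)
                        if bad:
                            ok = False
                            break
                        pos[anchor + m, 0] = x
                        pos[anchor + m, 1] = y
                        pos[anchor + m, 2] = z
                    if not ok:
                        continue
                    # closure: last loop monomer adjacent to the anchor
                    md = abs(x - ax) + abs(y - ay) + abs(z - az)
                    if md == 1:
                        closed = True
                        break
                if not closed:
                    return WALK_LOOP_BUDGET, anchor + k
            j = anchor + k + 1
    return WALK_OK, -1
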