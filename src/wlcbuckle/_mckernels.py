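"""Numba kernels for the discretized worm-like chain Monte Carlo.

Moves preserve bond lengths exactly (rigid rotations of sub-chains):

* crankshaft: rotate beads strictly between two anchors i < j about the
  i-j axis; end positions are invariant, so the end-to-end distance is
  conserved bit-for-bit in the fixed-extension ensemble.
* end pivot: rotate the tail (or head) of the chain about a random axis
  through an interior bead; used in the fixed-force ensemble where the
  ends fluctuate.

Energies are bending-only, k (1 - u_i . u_{i+1}) per joint, plus f R in
the fixed-force ensemble.  One seeded legacy RNG stream per kernel call
gives bit-reproducible trajectories.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def bending_energy_nb(pos, k_bend, ds):
    """k sum_j (1 - u_j . u_{j+1}) over interior joints."""
    n = pos.shape[0]
    e = 0.0
    for j in range(1, n - 1):
        dot = 0.0
        for c in range(3):
            dot += (pos[j, c] - pos[j - 1, c]) * (pos[j + 1, c] - pos[j, c])
        e += k_bend * (1.0 - dot / (ds * ds))
    return e


@njit(cache=True)
def _joint_energy(pos, m, k_bend, ds):
    """Energy of the joint at bead m (0 if m is an end bead)."""
    n = pos.shape[0]
    if m < 1 or m > n - 2:
        return 0.0
    dot = 0.0
    for c in range(3):
        dot += (pos[m, c] - pos[m - 1, c]) * (pos[m + 1, c] - pos[m, c])
    return k_bend * (1.0 - dot / (ds * ds))


@njit(cache=True)
def _rotate_about_axis(pos, lo, hi, ox, oy, oz, ax, ay, az, ang):
    """Rodrigues rotation of beads lo..hi (inclusive) about unit axis a
    through origin point o, in place."""
    ca = math.cos(ang)
    sa = math.sin(ang)
    for b in range(lo, hi + 1):
        vx = pos[b, 0] - ox
        vy = pos[b, 1] - oy
        vz = pos[b, 2] - oz
        dot = ax * vx + ay * vy + az * vz
        cx = ay * vz - az * vy
        cy = az * vx - ax * vz
        cz = ax * vy - ay * vx
        pos[b, 0] = ox + vx * ca + cx * sa + ax * dot * (1.0 - ca)
        pos[b, 1] = oy + vy * ca + cy * sa + ay * dot * (1.0 - ca)
        pos[b, 2] = oz + vz * ca + cz * sa + az * dot * (1.0 - ca)


@njit(cache=True)
def _end_distance(pos):
    n = pos.shape[0]
    dx = pos[n - 1, 0] - pos[0, 0]
    dy = pos[n - 1, 1] - pos[0, 1]
    dz = pos[n - 1, 2] - pos[0, 2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def mc_sweeps(pos, k_bend, ds, f_ext, use_pivot, delta, n_sweeps, seed,
              scratch):
    """Run n_sweeps Metropolis sweeps (one sweep = Nb attempted moves).

    use_pivot=False: crankshaft only (fixed-extension ensemble).
    use_pivot=True: 50/50 crankshaft / end-pivot with Boltzmann weight
    exp(-(E_bend + f_ext R)).
    Returns (accepted, attempted).  scratch is an (Nb,3) work array used
    to restore rejected pivot moves cheaply.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    accepted = 0
    attempted = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            attempted += 1
            do_pivot = use_pivot and np.random.random() < 0.5
            if not do_pivot:
                # crankshaft between anchors i < j (j >= i+2)
                i = np.random.randint(0, n - 2)
                j = np.random.randint(i + 2, n)
                ax = pos[j, 0] - pos[i, 0]
                ay = pos[j, 1] - pos[i, 1]
                az = pos[j, 2] - pos[i, 2]
                norm = math.sqrt(ax * ax + ay * ay + az * az)
                if norm < 1e-14:
                    continue
                ax /= norm
                ay /= norm
                az /= norm
                ang = (2.0 * np.random.random() - 1.0) * delta
                e_old = _joint_energy(pos, i, k_bend, ds) + _joint_energy(pos, j, k_bend, ds)
                for b in range(i + 1, j):
                    for c in range(3):
                        scratch[b, c] = pos[b, c]
                _rotate_about_axis(pos, i + 1, j - 1,
                                   pos[i, 0], pos[i, 1], pos[i, 2],
                                   ax, ay, az, ang)
                e_new = _joint_energy(pos, i, k_bend, ds) + _joint_energy(pos, j, k_bend, ds)
                dE = e_new - e_old
                if dE <= 0.0 or np.random.random() < math.exp(-dE):
                    accepted += 1
                else:
                    for b in range(i + 1, j):
                        for c in range(3):
                            pos[b, c] = scratch[b, c]
            else:
                # pivot the tail (or head) about a random axis through bead m
                m = np.random.randint(1, n - 1)
                tail = np.random.random() < 0.5
                ax = np.random.normal()
                ay = np.random.normal()
                az = np.random.normal()
                norm = math.sqrt(ax * ax + ay * ay + az * az)
                if norm < 1e-14:
                    continue
                ax /= norm
                ay /= norm
                az /= norm
                ang = (2.0 * np.random.random() - 1.0) * delta
                lo = m + 1 if tail else 0
                hi = n - 1 if tail else m - 1
                r_old = _end_distance(pos)
                e_old = _joint_energy(pos, m, k_bend, ds)
                for b in range(lo, hi + 1):
                    for c in range(3):
                        scratch[b, c] = pos[b, c]
                _rotate_about_axis(pos, lo, hi,
                                   pos[m, 0], pos[m, 1], pos[m, 2],
                                   ax, ay, az, ang)
                e_new = _joint_energy(pos, m, k_bend, ds)
                r_new = _end_distance(pos)
                dE = (e_new - e_old) + f_ext * (r_new - r_old)
                if dE <= 0.0 or np.random.random() < math.exp(-dE):
                    accepted += 1
                else:
                    for b in range(lo, hi + 1):
                        for c in range(3):
                            pos[b, c] = scratch[b, c]
    return accepted, attempted
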