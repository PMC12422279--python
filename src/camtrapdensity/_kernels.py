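"""Numba kernels for the correlated-random-walk and detection-zone hot loops.

Everything here is deterministic given the integer seed passed in: the
kernels use numba's internal re-implementation of ``np.random``, whose
state is private to the compiled function and initialised by
``np.random.seed`` at the top of each call.
"""

import numpy as np
from numba import njit

# One simulated trajectory touches ~10^5 steps and a training set touches
# ~10^9, so these loops are the only performance-critical code in the package.


@njit(cache=True)
def crw_walk(seed, n_steps, mean_step, sd_step, sd_turn_rad,
             cx, cy, hr_radius2, xlo, xhi, ylo, yhi):
    """Home-range-confined correlated random walk.

    Step lengths ~ Normal(mean_step, sd_step) truncated at zero (rejection);
    headings accumulate Normal(0, sd_turn_rad) increments; initial heading
    uniform on [0, 2pi).  A proposed step landing outside the home-range
    disc (radius^2 = hr_radius2, centre (cx, cy)) or outside the arena
    rectangle [xlo, xhi] x [ylo, yhi] is rejected and fully redrawn, up to
    100 attempts; the heading is then pointed at the home centre and lengths
    are resampled until a proposal lands inside (1,000-draw guard, after
    which the walker stays put for that step).

    Headings are compass-style: 0 = +y (north), increasing clockwise, so
    dx = L*sin(h), dy = L*cos(h).

    Returns (xs, ys): the n_steps step-endpoint coordinates. The walk
    starts at the home centre, which is not included in the output.
    """
    np.random.seed(seed)
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    x = cx
    y = cy
    heading = np.random.uniform(0.0, 2.0 * np.pi)
    for i in range(n_steps):
        accepted = False
        h = heading
        nx = x
        ny = y
        for _ in range(100):
            turn = np.random.normal(0.0, sd_turn_rad)
            length = np.random.normal(mean_step, sd_step)
            while length < 0.0:
                length = np.random.normal(mean_step, sd_step)
            h = heading + turn
            nx = x + length * np.sin(h)
            ny = y + length * np.cos(h)
            if ((nx - cx) ** 2 + (ny - cy) ** 2 <= hr_radius2
                    and xlo <= nx <= xhi and ylo <= ny <= yhi):
                accepted = True
                break
        if not accepted:
            h = np.arctan2(cx - x, cy - y)
            ok = False
            for _ in range(1000):
                length = np.random.normal(mean_step, sd_step)
                while length < 0.0:
                    length = np.random.normal(mean_step, sd_step)
                nx = x + length * np.sin(h)
                ny = y + length * np.cos(h)
                if ((nx - cx) ** 2 + (ny - cy) ** 2 <= hr_radius2
                        and xlo <= nx <= xhi and ylo <= ny <= yhi):
                    ok = True
                    break
            if not ok:
                nx = x
                ny = y
        x = nx
        y = ny
        heading = h
        xs[i] = x
        ys[i] = y
    return xs, ys


@njit(cache=True)
def sector_hits(xs, ys, cam_x, cam_y, facing_rad, radius2, halfwidth_rad):
    """All (step index, camera index) pairs where a position falls inside a
    camera's detection sector.

    A point is inside when its squared distance to the camera is
    <= radius2 and the compass bearing from camera to point is within
    +-halfwidth_rad of the camera's facing (inclusive boundaries). A point
    exactly at the camera position counts as inside.
    """
    step_idx = []
    cam_idx = []
    for i in range(xs.shape[0]):
        for c in range(cam_x.shape[0]):
            dx = xs[i] - cam_x[c]
            dy = ys[i] - cam_y[c]
            d2 = dx * dx + dy * dy
            if d2 <= radius2:
                if d2 == 0.0:
                    step_idx.append(i)
                    cam_idx.append(c)
                    continue
                bearing = np.arctan2(dx, dy)
                diff = bearing - facing_rad[c]
                while diff > np.pi:
                    diff -= 2.0 * np.pi
                while diff < -np.pi:
                    diff += 2.0 * np.pi
                if abs(diff) <= halfwidth_rad:
                    step_idx.append(i)
                    cam_idx.append(c)
    return np.array(step_idx, dtype=np.int64), np.array(cam_idx, dtype=np.int64)


@njit(cache=True)
def greedy_filter(times_ns, window_ns):
    """Greedy independence filter on a sorted int64 timestamp array.

    Keeps the first record, then each record whose gap to the last KEPT
    record strictly exceeds window_ns. Returns a boolean keep mask.
    """
    n = times_ns.shape[0]
    keep = np.zeros(n, dtype=np.bool_)
    last = np.int64(0)
    have = False
    for i in range(n):
        if not have or times_ns[i] - last > window_ns:
            keep[i] = True
            last = times_ns[i]
            have = True
    return keep
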