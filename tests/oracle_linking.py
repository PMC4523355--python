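"""Independent brute-force reference for the stage-wise linker.

Replays the same stage semantics as the production linker (active tracks,
gap allowances, null costs) but finds each stage's optimal assignment by
exhaustive enumeration over all injective track→detection mappings instead
of by Hungarian assignment.  Intended for tiny instances only.
"""

from itertools import combinations, permutations

import numpy as np


def stage_optimum(cand_states, dets, params):
    """Minimum stage cost over all feasible partial assignments.

    cand_states: list of (gap, x, y) for candidate tracks;
    dets: list of (x, y).  Cost model: link = d²/gap (only if
    d <= allowed(gap)), unmatched track or detection = max_disp².
    Returns (best_cost, best_assignment) with assignment as a tuple of
    (track_index, det_index) pairs.
    """
    n_c, n_d = len(cand_states), len(dets)
    null = params.max_disp**2
    best = n_c * null + n_d * null
    best_assign = ()
    for k in range(1, min(n_c, n_d) + 1):
        for track_sel in combinations(range(n_c), k):
            for det_sel in permutations(range(n_d), k):
                cost = 0.0
                ok = True
                for a, b in zip(track_sel, det_sel):
                    gap, px, py = cand_states[a]
                    dx = dets[b][0] - px
                    dy = dets[b][1] - py
                    d2 = dx * dx + dy * dy
                    if d2 > params.allowed(gap) ** 2:
                        ok = False
                        break
                    cost += d2 / gap
                if not ok:
                    continue
                cost += (n_c - k) * null + (n_d - k) * null
                if cost < best:
                    best = cost
                    best_assign = tuple(zip(track_sel, det_sel))
    return best, best_assign


def brute_force_link(frames, xs, ys, params):
    """Full linking by per-stage exhaustive enumeration.

    Returns (tracks, stage_costs) in the same form as the production
    linker's core: tracks as lists of detection indices.
    """
    frames = np.asarray(frames)
    tracks, last_frame, last_pos = [], [], []
    stage_costs = []
    for t in np.unique(frames):
        det_idx = [int(i) for i in np.flatnonzero(frames == t)]
        cand = [
            k for k in range(len(tracks))
            if 0 < t - last_frame[k] <= params.link_range
        ]
        cand_states = [
            (int(t - last_frame[k]), last_pos[k][0], last_pos[k][1]) for k in cand
        ]
        dets = [(float(xs[i]), float(ys[i])) for i in det_idx]
        cost, assign = stage_optimum(cand_states, dets, params)
        stage_costs.append(cost)
        matched = set()
        for a, b in assign:
            k, i = cand[a], det_idx[b]
            tracks[k].append(i)
            last_frame[k] = int(t)
            last_pos[k] = (float(xs[i]), float(ys[i]))
            matched.add(i)
        for i in det_idx:
            if i not in matched:
                tracks.append([i])
                last_frame.append(int(t))
                last_pos.append((float(xs[i]), float(ys[i])))
    return tracks, stage_costs
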