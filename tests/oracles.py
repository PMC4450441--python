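"""Independent brute-force oracle for the plane-linking problem.

Enumerates *every* criterion-respecting one-to-one matching between the
regions of each adjacent plane pair and keeps the one that is optimal under
the documented objective (maximum cardinality, then minimum total cost,
where cost = distance + 1e-6 * relative area difference + label epsilons).
Chains are then walked, cut at the z-extent cap and filtered by the minimum
plane count with a separate, simple implementation.  Shares only the
*definition* of the criteria/cost with the package, not its algorithms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rootmosaic.segmentation import PlaneSegmentation


def _pair_cost(dist, rel, la, lb):
    return dist + 1e-6 * rel + 1e-9 * la + 1e-12 * lb


def brute_force_matching(regions_a: pd.DataFrame, regions_b: pd.DataFrame, criteria):
    """Exhaustive optimal matching between two region tables."""
    la = regions_a["label"].to_numpy()
    lb = regions_b["label"].to_numpy()
    pa = regions_a[["row", "col"]].to_numpy(float)
    pb = regions_b[["row", "col"]].to_numpy(float)
    aa = regions_a["area_px"].to_numpy(float)
    ab = regions_b["area_px"].to_numpy(float)
    nA, nB = len(la), len(lb)
    cand = []
    for i in range(nA):
        row = []
        for j in range(nB):
            d = float(np.hypot(pa[i, 0] - pb[j, 0], pa[i, 1] - pb[j, 1]))
            rel = abs(aa[i] - ab[j]) / max(aa[i], ab[j])
            if d <= criteria.max_centroid_dist and rel <= criteria.max_area_change:
                row.append((j, _pair_cost(d, rel, la[i], lb[j])))
        cand.append(row)

    best = {"key": None, "pairs": None}

    def rec(i, used, pairs, cost):
        if i == nA:
            key = (-len(pairs), cost)
            if best["key"] is None or key < best["key"]:
                best["key"] = key
                best["pairs"] = list(pairs)
            return
        rec(i + 1, used, pairs, cost)  # leave region i unmatched
        for j, c in cand[i]:
            if j not in used:
                used.add(j)
                pairs.append((int(la[i]), int(lb[j])))
                rec(i + 1, used, pairs, cost + c)
                pairs.pop()
                used.remove(j)

    rec(0, set(), [], 0.0)
    return best["pairs"] or []


def brute_force_link(segs, criteria, min_planes=2):
    """Full linking oracle: exhaustive matchings + simple chain walking."""
    segs = sorted(segs, key=lambda s: s.plane_index)
    by_plane = {s.plane_index: s for s in segs}
    forward = {}
    for s in segs:
        nxt = by_plane.get(s.plane_index + 1)
        if nxt is None:
            continue
        for a, b in brute_force_matching(s.regions, nxt.regions, criteria):
            forward[(s.plane_index, a)] = (nxt.plane_index, b)
    has_in = set(forward.values())
    chains = []
    for s in segs:
        for lab in sorted(s.regions["label"].tolist()):
            node = (s.plane_index, int(lab))
            if node in has_in:
                continue
            chain = [node]
            while chain[-1] in forward:
                chain.append(forward[chain[-1]])
            for k in range(0, len(chain), criteria.max_z_extent_planes):
                piece = chain[k : k + criteria.max_z_extent_planes]
                if len(piece) >= min_planes:
                    chains.append(tuple(piece))
    return sorted(chains)


def random_instance(rng: np.random.Generator):
    """A random small linking instance (<= 5 planes, <= 50 regions total).

    Mixes diffuse and clustered centroid layouts so that both sparse and
    competitive (many-candidate) matchings are exercised.
    """
    n_planes = int(rng.integers(2, 6))
    clustered = rng.random() < 0.5
    centres = rng.uniform(10, 90, size=(4, 2)) if clustered else None
    segs = []
    total = 0
    for p in range(n_planes):
        n = int(rng.integers(1, 9))
        n = min(n, 50 - total)
        total += n
        recs = []
        for i in range(n):
            if clustered:
                c = centres[rng.integers(0, len(centres))]
                pos = c + rng.normal(0, 8, 2)
            else:
                pos = rng.uniform(0, 100, 2)
            recs.append(
                {
                    "label": i + 1,
                    "row": float(pos[0]),
                    "col": float(pos[1]),
                    "area_px": float(rng.lognormal(np.log(120), 0.4)),
                }
            )
        segs.append(PlaneSegmentation.from_records(p, recs))
        if total >= 50:
            break
    return segs
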