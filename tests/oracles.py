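"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a result from first principles in a deliberately
different style from the package code: a day-by-day grid scan for the
refill-gap episode rule, a union-find transitive closure for same-event
merging.
"""

from __future__ import annotations

import numpy as np


def episode_oracle(fill_days, other_fills, supply, censor_day, censor_reason,
                   gap=60, swin=60, disc_at="supply_end"):
    """Day-grid simulation of the persistence rule.

    Walks calendar days one at a time, accepting index refills that arrive
    no later than the grace deadline, detecting a switch as the first
    other-class fill strictly inside the post-supply switch window, and
    otherwise discontinuing once the grace and switch windows have both
    passed unused.
    """
    fills = sorted({int(f) for f in fill_days if f <= censor_day})
    other_map: dict[int, str] = {}
    for day, cls in sorted((int(d), c) for d, c in other_fills):
        other_map.setdefault(day, cls)

    exp = fills[0] + supply
    if exp >= censor_day:
        return censor_day, censor_reason, None
    fills_set = set(fills)
    d = fills[0]
    while True:
        d += 1
        if d in fills_set and d <= exp + gap:
            exp = d + supply
            if exp >= censor_day:
                return censor_day, censor_reason, None
            continue
        if exp < d <= exp + swin and d in other_map and d <= censor_day:
            return d, "switched", other_map[d]
        if d > exp + max(gap, swin):
            if disc_at == "grace_end":
                end = exp + gap
                if end >= censor_day:
                    return censor_day, censor_reason, None
                return end, "discontinued", None
            return exp, "discontinued", None


def merge_oracle(diagnoses, window=90):
    """Transitive closure of the pairwise '<= window days apart, same person,
    same site' relation via union-find; returns sorted
    (person, site, event_date, n_diagnoses) tuples."""
    items = list(diagnoses)  # (person, site, day)
    n = len(items)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            pi, si, di = items[i]
            pj, sj, dj = items[j]
            if pi == pj and si == sj and abs(di - dj) <= window:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = []
    for idx in comps.values():
        person, site, _ = items[idx[0]]
        days = [items[i][2] for i in idx]
        out.append((person, site, min(days), len(idx)))
    return sorted(out)


def random_fill_case(rng, max_fills=12, max_supply=200):
    """A random episode-builder test case on integer days."""
    supply = int(rng.integers(7, max_supply + 1))
    n_fills = int(rng.integers(1, max_fills + 1))
    gaps = rng.integers(0, 160, size=n_fills - 1)
    fills = np.concatenate([[0], np.cumsum(supply + gaps)])[:n_fills]
    n_other = int(rng.integers(0, 4))
    others = [
        (int(rng.integers(1, max(2, fills[-1] + supply + 150))),
         rng.choice(["oral_bisphosphonate", "raloxifene", "hrt"]))
        for _ in range(n_other)
    ]
    censor_day = int(rng.integers(30, fills[-1] + supply + 400))
    censor_reason = str(rng.choice(["death", "disenrolled", "admin_end"]))
    return dict(fill_days=fills.tolist(), other_fills=others, supply=supply,
                censor_day=censor_day, censor_reason=censor_reason)
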