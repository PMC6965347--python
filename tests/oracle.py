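"""Brute-force reference implementation of the full detection pipeline.

Used only on micro-instances (a few series, a handful of points, short
observation periods). Everything is recomputed with plain Python loops
and exhaustive enumeration: candidate intervals from nearest-follower
distances, window hits by double loop, exact tail probabilities by
summing over all hit configurations, greedy pairing, and the
completeness competition. No numpy/scipy on the statistics path.
"""

import itertools


def _sample_end(t, boundaries):
    return min(b for b in boundaries if b >= t)


def _sample_index(t, boundaries):
    for i, b in enumerate(boundaries):
        if t <= b:
            return i
    raise ValueError(t)


def _tail_enumeration(probs, k):
    if k <= 0:
        return 1.0
    total = 0.0
    for hits in itertools.product((0, 1), repeat=len(probs)):
        if sum(hits) >= k:
            prob = 1.0
            for h, p in zip(hits, probs):
                prob *= p if h else 1.0 - p
            total += prob
    return min(1.0, total)


def _window_hits(a_pts, b_pts, d1, d2, boundaries):
    hits = 0
    for a in a_pts:
        hi = min(a + d2, _sample_end(a, boundaries))
        if any(a + d1 <= b <= hi for b in b_pts):
            hits += 1
    return hits


def _best_ci(a_pts, b_pts, T, params, boundaries):
    """Mirror of the critical-interval search, by exhaustive loops."""
    a_pts, b_pts = sorted(a_pts), sorted(b_pts)
    if not a_pts or not b_pts or len(b_pts) >= T:
        return None
    d_max = T - 1 if params.d_max is None else min(params.d_max, T - 1)
    nearest = set()
    for a in a_pts:
        cap = min(d_max, _sample_end(a, boundaries) - a)
        ds = [b - a for b in b_pts if 0 <= b - a <= cap]
        if ds:
            nearest.add(min(ds))
    dists = sorted(nearest)
    if not dists:
        return None
    w_max = max(1, T // len(b_pts))
    n_tests = len(dists)
    best = None
    for i, d1 in enumerate(dists):
        for d2 in dists[i:]:
            if d2 - d1 + 1 > w_max:
                break
            hits = _window_hits(a_pts, b_pts, d1, d2, boundaries)
            if hits < params.n_min:
                continue
            probs = []
            for a in a_pts:
                w = max(0, min(a + d2, _sample_end(a, boundaries)) - (a + d1) + 1)
                probs.append(1.0 - (1.0 - len(b_pts) / T) ** w)
            p = _tail_enumeration(probs, hits)
            adjusted = p if n_tests <= 1 else 1.0 - (1.0 - min(p, 1.0)) ** n_tests
            if adjusted > params.alpha:
                continue
            key = (p, d2 - d1, d1)
            if best is None or key < best[0]:
                best = (key, d1, d2, p, hits)
    if best is None:
        return None
    _, d1, d2, p, hits = best
    return d1, d2, p, hits


# --- pattern bookkeeping (signatures mirror the engine's format) ----------


def _terminals(sig):
    if sig[0] == "t":
        return (sig[1],)
    return _terminals(sig[1]) + _terminals(sig[2])


def _flatten(sig, occ):
    if sig[0] == "t":
        return [occ]
    return _flatten(sig[1], occ[0]) + _flatten(sig[2], occ[1])


def _points(sig, occ):
    labels = _terminals(sig)
    return set(zip(labels, _flatten(sig, occ)))


class _Pat:
    def __init__(self, sig, occs, max_p):
        self.sig = sig
        self.occs = list(occs)  # occurrence trees
        self.max_p = max_p

    @property
    def labels(self):
        return _terminals(self.sig)

    @property
    def m(self):
        return len(self.labels)

    def flats(self):
        return tuple(tuple(_flatten(self.sig, o)) for o in self.occs)

    def signature(self):
        return (self.sig, self.flats())


def _pairing(left, right, d1, d2, boundaries):
    lefts = sorted(left.occs, key=lambda o: _flatten(left.sig, o)[0])
    rights = sorted(right.occs, key=lambda o: _flatten(right.sig, o)[0])
    used = [False] * len(rights)
    pairs = []
    for lo in lefts:
        e = _flatten(left.sig, lo)[-1]
        lp = _points(left.sig, lo)
        for j, ro in enumerate(rights):
            if used[j]:
                continue
            s = _flatten(right.sig, ro)[0]
            if s - e > d2:
                break
            if s - e >= d1 and _sample_index(e, boundaries) == _sample_index(s, boundaries):
                if lp & _points(right.sig, ro):
                    continue
                used[j] = True
                pairs.append((lo, ro))
                break
    pairs.sort(key=lambda pr: _flatten(left.sig, pr[0])[0])
    return pairs


def _is_subseq(short, long):
    it = iter(long)
    return all(any(x == y for y in it) for x in short)


def _compete(pool):
    best = {}
    order = []
    for p in pool:
        key = (p.labels, p.flats())
        if key not in best:
            best[key] = p
            order.append(key)
        elif p.max_p < best[key].max_p:
            best[key] = p
    pool = [best[k] for k in order]
    survivors = []
    for p in pool:
        dropped = False
        for q in pool:
            if q is p or len(q.labels) <= len(p.labels) or len(q.occs) != len(p.occs):
                continue
            if not _is_subseq(p.labels, q.labels):
                continue
            used = [False] * len(q.occs)
            ok = True
            for po in p.occs:
                pp = _points(p.sig, po)
                for j, qo in enumerate(q.occs):
                    if not used[j] and pp <= _points(q.sig, qo):
                        used[j] = True
                        break
                else:
                    ok = False
                    break
            if ok:
                dropped = True
                break
        if not dropped:
            survivors.append(p)
    return survivors


def detect_tpatterns_oracle(data, params):
    """Set of (structure signature, flat occurrences) the engine must match."""
    boundaries = data.sample_boundaries
    terminals = [
        _Pat(("t", s.label), list(s.points), 0.0)
        for s in data.series
        if s.points
    ]
    patterns = []
    built = set()
    for _ in range(params.max_levels):
        working = terminals + patterns
        new = []
        for P in working:
            for Q in working:
                if P is Q or P.m + Q.m > params.max_length:
                    continue
                ends = sorted({_flatten(P.sig, o)[-1] for o in P.occs})
                starts = sorted({_flatten(Q.sig, o)[0] for o in Q.occs})
                found = _best_ci(ends, starts, data.T, params, boundaries)
                if found is None:
                    continue
                d1, d2, p, hits = found
                occs = _pairing(P, Q, d1, d2, boundaries)
                if len(occs) < params.n_min:
                    continue
                cand = _Pat(
                    ("p", P.sig, Q.sig, d1, d2),
                    occs,
                    max(p, P.max_p, Q.max_p),
                )
                if cand.signature() in built:
                    continue
                built.add(cand.signature())
                new.append(cand)
        if not new:
            break
        survivors = _compete(patterns + new)
        if {s.signature() for s in survivors} == {p.signature() for p in patterns}:
            break
        patterns = survivors
    return {p.signature() for p in patterns}
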