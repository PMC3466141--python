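"""Independent brute-force oracle for the partially paired permutation test.

Everything here is computed from first principles (positional midranks,
exhaustive enumeration of within-pair swaps crossed with unpaired label
reassignments) without touching the package's permutation engine, so tests
can compare the two routes.
"""

from itertools import combinations, product

TOL = 1e-9


def midranks_oracle(values):
    """Midranks computed by counting, not sorting libraries."""
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        eq = sum(1 for w in values if w == v)
        ranks.append(less + (eq + 1) / 2)
    return ranks


def brute_force_test(peer, listed):
    """Exhaustive null distribution of the peer rank-sum for scalar-valued maps.

    Returns (observed, p_one_sided, p_two_sided, p_tie).
    """
    paired_keys = sorted(set(peer) & set(listed), key=str)
    peer_only = sorted(set(peer) - set(listed), key=str)
    listed_only = sorted(set(listed) - set(peer), key=str)
    pairs = [(peer[k], listed[k]) for k in paired_keys]
    unpaired = [peer[k] for k in peer_only] + [listed[k] for k in listed_only]
    n_peer_unp = len(peer_only)

    k = len(pairs)
    values = [a for a, _ in pairs] + [b for _, b in pairs] + unpaired
    ranks = midranks_oracle(values)

    obs = sum(ranks[i] for i in range(k)) + sum(
        ranks[2 * k + j] for j in range(n_peer_unp)
    )

    stats = []
    m = len(unpaired)
    for pattern in product((0, 1), repeat=k):
        base = sum(ranks[k + i] if sw else ranks[i] for i, sw in enumerate(pattern))
        for sel in combinations(range(m), n_peer_unp):
            stats.append(base + sum(ranks[2 * k + j] for j in sel))

    n = len(stats)
    e = sum(stats) / n
    p_one = sum(s <= obs + TOL for s in stats) / n
    p_two = sum(abs(s - e) >= abs(obs - e) - TOL for s in stats) / n
    p_tie = sum(abs(s - obs) <= TOL for s in stats) / n
    return obs, p_one, p_two, p_tie


def random_fixture(rng, max_paired=10, allow_ties=True):
    """A random small partially paired instance as (peer_map, listed_map)."""
    n_paired = int(rng.integers(1, max_paired + 1))
    n_peer_only = int(rng.integers(0, 3))
    n_listed_only = int(rng.integers(0, 4))

    def draw():
        v = float(rng.integers(0, 8)) if allow_ties else float(rng.random())
        return v

    peer, listed = {}, {}
    for i in range(n_paired):
        peer[f"s{i}"] = draw()
        listed[f"s{i}"] = draw()
    for i in range(n_peer_only):
        peer[f"p{i}"] = draw()
    for i in range(n_listed_only):
        listed[f"l{i}"] = draw()
    return peer, listed
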