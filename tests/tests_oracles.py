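"""Independent brute-force oracles shared by the test modules.

These deliberately share no code with the implementation paths they check.
"""

import itertools


def brute_force_gain_sequences(interfaces):
    """All step-gain sequences reachable by always merging a maximal-gain
    component pair, by exhaustive recursion over merge orders."""
    chains = sorted({c for i in interfaces for c in i.chain_pair})

    def gain(c1, c2):
        total = 0.0
        for i in interfaces:
            a, b = i.chain_pair
            if (a in c1 and b in c2) or (a in c2 and b in c1):
                total += i.bsa_total
        return total

    results = set()

    def recurse(components, gains_so_far):
        pair_gains = [
            (gain(c1, c2), c1, c2)
            for c1, c2 in itertools.combinations(components, 2)
        ]
        positive = [pg for pg in pair_gains if pg[0] > 0]
        if not positive:
            results.add(tuple(gains_so_far))
            return
        best = max(pg[0] for pg in positive)
        for g, c1, c2 in positive:
            if g < best - 1e-9:
                continue
            nxt = [c for c in components if c is not c1 and c is not c2]
            nxt.append(c1 | c2)
            recurse(nxt, gains_so_far + [g])

    recurse([frozenset([c]) for c in chains], [])
    return results
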