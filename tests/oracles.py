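"""Independent reference implementations used as test oracles."""

import numpy as np


def strict_extrema(distance, elevation):
    """All strict interior extrema of a sequence, as (dist, elev, kind)."""
    out = []
    for i in range(1, len(elevation) - 1):
        if elevation[i] > elevation[i - 1] and elevation[i] > elevation[i + 1]:
            out.append((float(distance[i]), float(elevation[i]), "max"))
        elif elevation[i] < elevation[i - 1] and elevation[i] < elevation[i + 1]:
            out.append((float(distance[i]), float(elevation[i]), "min"))
    return out


def brute_force_prune(extrema, threshold):
    """Exhaustive smallest-amplitude-first pair pruning with tie branching.

    Explores every admissible removal order (branching over all adjacent
    pairs tied at the current smallest amplitude) and returns the set of
    reachable end states.  A deterministic pruner must produce the single
    element of this set when it is a singleton.
    """
    seen = {}

    def rec(state):
        if state in seen:
            return seen[state]
        if len(state) < 2:
            result = frozenset([state])
        else:
            amps = [abs(state[i + 1][1] - state[i][1]) for i in range(len(state) - 1)]
            smallest = min(amps)
            if smallest >= threshold:
                result = frozenset([state])
            else:
                outs = set()
                for i, a in enumerate(amps):
                    if a == smallest:
                        outs |= rec(state[:i] + state[i + 2 :])
                result = frozenset(outs)
        seen[state] = result
        return result

    return rec(tuple(extrema))


def max_alternating_count(extrema, threshold):
    """DP upper bound: longest alternating subsequence with adjacent
    amplitude >= threshold (ignores pruning reachability)."""
    m = len(extrema)
    if m == 0:
        return 0
    dp = [1] * m
    for i in range(m):
        for j in range(i):
            if extrema[j][2] != extrema[i][2] and abs(
                extrema[i][1] - extrema[j][1]
            ) >= threshold:
                dp[i] = max(dp[i], dp[j] + 1)
    return max(dp)


def random_trig_profile(rng, n=None, n_components=(2, 5), freq=(1, 4), amp=(0.2, 3.0)):
    """Smooth random profile with a bounded number of extrema."""
    n = n or int(rng.integers(50, 201))
    x = np.linspace(0.0, 1.0, n)
    z = np.zeros(n)
    for _ in range(int(rng.integers(*n_components))):
        z += rng.uniform(*amp) * np.sin(
            2 * np.pi * int(rng.integers(*freq)) * x + rng.uniform(0, 2 * np.pi)
        )
    return x * 500.0, z
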