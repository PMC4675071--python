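"""Independent brute-force oracles used to validate the package's statistics.

These deliberately avoid the package's own code paths: midranks are computed
by direct counting and the signed-rank null distribution by explicit
enumeration of all 2^n sign assignments.
"""

from __future__ import annotations

from itertools import product


def enumerate_signed_rank_p(diff) -> float:
    """Two-sided signed-rank p by exhaustive sign-assignment enumeration.

    Zeros are dropped; tied absolute differences get midranks (computed by
    counting, on a doubled-integer scale); the p-value is the symmetric
    two-tailed probability 2 * min(P(W+ <= w), P(W+ >= w)), capped at 1.
    """
    d = [float(x) for x in diff if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = [abs(x) for x in d]
    # doubled midrank of item i: 2 * (#smaller) + (#equal incl. self) + (#equal) - ...
    doubled = []
    for i in range(n):
        less = sum(1 for a in absd if a < absd[i])
        equal = sum(1 for a in absd if a == absd[i])
        doubled.append(2 * less + equal + 1)  # = 2 * midrank
    w_obs = sum(r for r, x in zip(doubled, d) if x > 0)

    n_le = n_ge = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(doubled, signs) if s)
        if w <= w_obs:
            n_le += 1
        if w >= w_obs:
            n_ge += 1
    total = 2**n
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def bh_step_up(p_values) -> list[float]:
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
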