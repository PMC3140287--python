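"""Independent brute-force oracles, deliberately coded apart from the
production solver: plain interval-halving bisection on the cohort risk
balance, and direct re-derivations of the scenario formulas from first
principles. Used to freeze expected values and to cross-check the package.
"""

from __future__ import annotations


def bisect_p0(conditions, r, cap, iters=200):
    """Bisection for the baseline risk on [0, r / (1 - sum(prev))].

    ``conditions`` is a sequence of (prevalence, relative_risk) tuples.
    After 200 halvings the bracket is far below 1e-12 wide.
    """
    total_prev = sum(p for p, _ in conditions)
    assert total_prev < 1.0

    def balance(p0):
        carrier = sum(p * min(rr * p0, cap) for p, rr in conditions)
        return carrier + (1.0 - total_prev) * p0 - r

    lo, hi = 0.0, r / (1.0 - total_prev)
    assert balance(lo) <= 0.0 <= balance(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if balance(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def scenario_quantities(conditions, r, cap, n, efficacy, therapy_cost, screened):
    """(screen cost, therapy cost, expected complications) for a screening
    scenario, derived directly from the per-condition formulas.

    ``conditions`` is a sequence of (name, prev, rr, sens, assay_cost);
    ``screened`` a set of names.
    """
    p0 = bisect_p0([(p, rr) for _, p, rr, _, _ in conditions], r, cap)
    s_cost = sum(c for nm, _, _, _, c in conditions if nm in screened)
    a_cost = therapy_cost * sum(p * s for nm, p, _, s, _ in conditions if nm in screened)
    detected = sum(
        s * n * p * min(rr * p0, cap)
        for nm, p, rr, s, _ in conditions
        if nm in screened
    )
    return s_cost, a_cost, n * r - efficacy * detected
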