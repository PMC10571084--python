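"""Independent brute-force oracles for the speciation solver tests.

These deliberately avoid the package's Newton solver: the three-reaction
sensor/Mg/ATP system is solved by nested interval bisection on the two
free-concentration unknowns (free Mg and free ATP), with free sensor
eliminated analytically.
"""

from __future__ import annotations


def bound_1to1_bruteforce(s_total, m_total, kd, iters=200):
    """1:1 bound complex by bisection on free metal (no quadratic)."""
    lo, hi = 0.0, m_total

    def mg_balance(m):
        s = s_total / (1.0 + m / kd)
        return m + s * m / kd - m_total

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mg_balance(mid) < 0:
            lo = mid
        else:
            hi = mid
    m = 0.5 * (lo + hi)
    s = s_total / (1.0 + m / kd)
    return s * m / kd


def ternary_system_bisection(
    s_total, mg_total, atp_total, kd_sm, kd_mgatp, kd_ternary, iters=200
):
    """Solve S+Mg<->SM, Mg+ATP<->MgATP, S+MgATP<->S.Mg.ATP by nested bisection.

    Unknowns: free Mg (m) and free ATP (a). Given (m, a), free sensor is
    s = S_t / (1 + m/K1 + m a/(K2 K3)). The inner bisection solves the
    ATP balance for a at fixed m; the outer solves the Mg balance for m.
    Returns a dict of all six species concentrations.
    """
    K1, K2, K3 = kd_sm, kd_mgatp, kd_ternary

    def free_sensor(m, a):
        return s_total / (1.0 + m / K1 + m * a / (K2 * K3))

    def atp_balance(a, m):
        s = free_sensor(m, a)
        return a * (1.0 + m / K2 + s * m / (K2 * K3)) - atp_total

    def solve_a(m):
        lo, hi = 0.0, atp_total
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if atp_balance(mid, m) < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def mg_balance(m):
        a = solve_a(m)
        s = free_sensor(m, a)
        bound = s * m / K1 + m * a / K2 + s * m * a / (K2 * K3)
        return m + bound - mg_total

    lo, hi = 0.0, mg_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mg_balance(mid) < 0:
            lo = mid
        else:
            hi = mid
    m = 0.5 * (lo + hi)
    a = solve_a(m)
    s = free_sensor(m, a)
    return {
        "sensor": s,
        "Mg": m,
        "ATP": a,
        "sensor_Mg": s * m / K1,
        "MgATP": m * a / K2,
        "sensor_Mg_ATP": s * m * a / (K2 * K3),
    }
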