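"""Independent brute-force Mamdani oracle, pure Python.

Re-implements pi/triangle memberships, connective semantics and centroid
defuzzification with plain loops and ``math`` only, reading the parameters
off the system's declared set objects.  Used to cross-check the vectorized
engine; shares no evaluation code with it.
"""

import math

from heatwatch.fuzzy import FuzzySystem, PiMembership, RiskInput, TriMembership


def _smooth(x, a, b):
    if b <= a:
        return 1.0 if x >= a else 0.0
    if x <= a:
        return 0.0
    if x >= b:
        return 1.0
    t = (x - a) / (b - a)
    return 2 * t * t if t <= 0.5 else 1 - 2 * (1 - t) * (1 - t)


def _mu(mf, x):
    if isinstance(mf, PiMembership):
        if mf.b <= x <= mf.c:
            return 1.0
        return min(_smooth(x, mf.a, mf.b), 1.0 - _smooth(x, mf.c, mf.d))
    if isinstance(mf, TriMembership):
        if x <= mf.a or x >= mf.c:
            return 1.0 if x == mf.b else 0.0
        if x <= mf.b:
            return (x - mf.a) / (mf.b - mf.a) if mf.b > mf.a else 1.0
        return (mf.c - x) / (mf.c - mf.b) if mf.c > mf.b else 1.0
    raise TypeError(type(mf))


def oracle_infer(system: FuzzySystem, x: RiskInput, step: float = 0.01) -> float:
    crisp = {
        "heart_rate": x.h,
        "core_temp": x.ct,
        "work_intensity": x.w,
        "time_interval": x.t,
    }
    degrees = {}
    for name, var in system.inputs.items():
        lo, hi = var.universe
        v = min(max(crisp[name], lo), hi)
        degrees[name] = {s: _mu(mf, v) for s, mf in var.sets.items()}

    strengths = []
    for rule in system.rules:
        clause_vals = []
        for var, sets in rule.clauses.items():
            mu = max(degrees[var][s] for s in sets)
            if var in rule.negate:
                mu = 1.0 - mu
            clause_vals.append(mu)
        s = min(clause_vals) if rule.op == "and" else max(clause_vals)
        strengths.append((rule.consequent, s))

    lo, hi = system.output.universe
    n = int(round((hi - lo) / step))
    num = 0.0
    den = 0.0
    for i in range(n + 1):
        z = lo + i * step
        agg = 0.0
        for cons, s in strengths:
            if s > 0:
                agg = max(agg, min(s, _mu(system.output.sets[cons], z)))
        num += z * agg
        den += agg
    if den == 0:
        raise RuntimeError("oracle: empty aggregate")
    return num / den
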