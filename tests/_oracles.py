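"""Independent brute-force oracles for the accumulation and statistics ops.

Straight-line scalar transcriptions, deliberately written without reusing
any code path from the package: the package is vectorised/batched, these
are plain per-hour loops and Σ-formulas.
"""

import math

SLP = 1.6
TETMLT = 277.0
E0 = 4153.5
E1 = 12888.8
A0 = 139500.0
A1 = 2.567e18


def dynamic_cp_oracle(temps_c):
    """Scalar transcription of the Dynamic-model hourly recursion; returns
    the list of cumulative chill portions."""
    inter_s = 0.0
    total = 0.0
    out = []
    for tc in temps_c:
        tk = tc + 273.0
        ftmprt = SLP * TETMLT * (tk - TETMLT) / tk
        sr = math.exp(ftmprt)
        xi = sr / (1.0 + sr)
        xs = A0 / A1 * math.exp(-(E0 - E1) / tk)
        ak1 = A1 * math.exp(-E1 / tk)
        inter_e = xs - (xs - inter_s) * math.exp(-ak1)
        delt = xi * inter_e if inter_e >= 1.0 else 0.0
        inter_s = inter_e - delt
        total += delt
        out.append(total)
    return out


def utah_weight_oracle(t):
    if t <= 1.4:
        return 0.0
    if t <= 2.4:
        return 0.5
    if t <= 9.1:
        return 1.0
    if t <= 12.4:
        return 0.5
    if t <= 15.9:
        return 0.0
    if t <= 18.0:
        return -0.5
    return -1.0


def utah_oracle(temps_c):
    total = 0.0
    out = []
    for t in temps_c:
        total += utah_weight_oracle(t)
        out.append(total)
    return out


def weinberger_oracle(temps_c):
    return sum(1 for t in temps_c if t < 7.2)


def gdh_oracle(temps_c):
    total = 0.0
    for t in temps_c:
        eff = min(t, 25.0)
        if eff > 4.5:
            total += eff - 4.5
    return total


def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def bland_altman_oracle(a, b):
    n = len(a)
    d = [x - y for x, y in zip(a, b)]
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    sd = math.sqrt(var)
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    inside = sum(1 for x in d if lo <= x <= hi) / n
    return mean, sd, lo, hi, inside
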