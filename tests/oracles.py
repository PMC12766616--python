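"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over the defining formulas,
deliberately ignoring the vectorized/streaming structure of the package
code it checks.
"""

import math


def cov_oracle(values, ddof=1):
    vals = [abs(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    ss = sum((v - mean) ** 2 for v in vals)
    sd = math.sqrt(ss / (n - ddof))
    return sd / mean


def censoring_km_oracle(times, events, t_eval, left=True):
    """Kaplan-Meier survival of the censoring distribution at t_eval."""
    prod = 1.0
    for u in sorted(set(times)):
        if (u < t_eval) if left else (u <= t_eval):
            at_risk = sum(1 for t in times if t >= u)
            n_cens = sum(1 for t, e in zip(times, events)
                         if t == u and not e)
            prod *= 1.0 - n_cens / at_risk
    return prod


def uno_c_oracle(risk, times, events, tau):
    """O(n^2) IPCW concordance sum."""
    n = len(times)
    num = den = 0.0
    for i in range(n):
        if not events[i] or times[i] >= tau:
            continue
        g = censoring_km_oracle(times, events, times[i], left=True)
        w = 1.0 / g ** 2
        for j in range(n):
            if times[j] > times[i]:
                den += w
                if risk[i] > risk[j]:
                    num += w
                elif risk[i] == risk[j]:
                    num += 0.5 * w
    return num / den


def brier_oracle(pred, times, events, horizon):
    n = len(times)
    g_h = censoring_km_oracle(times, events, horizon, left=False)
    total = 0.0
    for i in range(n):
        if times[i] <= horizon and events[i]:
            g = censoring_km_oracle(times, events, times[i], left=True)
            total += (pred[i] - 1.0) ** 2 / g
        elif times[i] > horizon:
            total += (pred[i] - 0.0) ** 2 / g_h
    return total / n


def nri_oracle(risk_old, risk_new, times, events, horizon):
    n = len(times)
    w_e = [0.0] * n
    w_ne = [0.0] * n
    g_h = censoring_km_oracle(times, events, horizon, left=False)
    for i in range(n):
        if times[i] <= horizon and events[i]:
            w_e[i] = 1.0 / censoring_km_oracle(times, events, times[i],
                                               left=True)
        elif times[i] > horizon:
            w_ne[i] = 1.0 / g_h
    se, sne = sum(w_e), sum(w_ne)
    up = [risk_new[i] > risk_old[i] for i in range(n)]
    down = [risk_new[i] < risk_old[i] for i in range(n)]
    p_up_e = sum(w for w, u in zip(w_e, up) if u) / se
    p_down_e = sum(w for w, d in zip(w_e, down) if d) / se
    p_up_ne = sum(w for w, u in zip(w_ne, up) if u) / sne if sne else 0.0
    p_down_ne = sum(w for w, d in zip(w_ne, down) if d) / sne if sne else 0.0
    return 100.0 * ((p_up_e - p_down_e) + (p_down_ne - p_up_ne))


def mw_u_oracle(x, y):
    """Mann-Whitney U for x by direct pair counting (ties = 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mw_normal_p_oracle(x, y):
    """Two-sided tie-corrected normal p with continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u = mw_u_oracle(x, y)
    mu = n1 * n2 / 2.0
    pooled = sorted(list(x) + list(y))
    tie_term = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie_term += t ** 3 - t
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    return math.erfc(z / math.sqrt(2.0))


def logrank_trend_oracle(times, events, group_labels, scores):
    """Score-test trend statistic from explicit per-event-time tables."""
    u = var = 0.0
    event_times = sorted({t for t, e in zip(times, events) if e})
    for tj in event_times:
        risk = [(s, e, t) for t, e, g in zip(times, events, group_labels)
                for s in [scores[g]] if t >= tj]
        n_j = len(risk)
        if n_j < 2:
            continue
        d_j = sum(1 for s, e, t in risk if e and t == tj)
        s_vals = [s for s, _, _ in risk]
        mean_s = sum(s_vals) / n_j
        mean_s2 = sum(s * s for s in s_vals) / n_j
        obs = sum(s for s, e, t in risk if e and t == tj)
        u += obs - d_j * mean_s
        var += d_j * (n_j - d_j) / (n_j - 1) * (mean_s2 - mean_s ** 2)
    return u ** 2 / var if var > 0 else 0.0


def km_oracle(times, events):
    """Hand product-limit estimator: [(t, S(t))] at event times."""
    out = []
    s = 1.0
    for tj in sorted({t for t, e in zip(times, events) if e}):
        n_j = sum(1 for t in times if t >= tj)
        d_j = sum(1 for t, e in zip(times, events) if e and t == tj)
        s *= 1.0 - d_j / n_j
        out.append((tj, s))
    return out


def cox_loglik_oracle(beta, x, times, events):
    """Partial log-likelihood for one covariate, no ties."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = sum(math.exp(beta * x[j]) for j in range(len(times))
                   if times[j] >= times[i])
        ll += beta * x[i] - math.log(risk)
    return ll
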