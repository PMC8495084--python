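"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops and sums — no numpy
linear algebra, no scipy statistics — so the oracles share no code path with
the package implementations they check.
"""

import math


def oracle_fixed_pool(values, variances):
    """Inverse-variance fixed-effect estimate and SE by explicit summation."""
    sw = 0.0
    swx = 0.0
    for x, v in zip(values, variances):
        w = 1.0 / v
        sw += w
        swx += w * x
    return swx / sw, math.sqrt(1.0 / sw)


def oracle_dl_tau2(values, variances):
    """DerSimonian-Laird between-study variance by explicit summation."""
    est, _ = oracle_fixed_pool(values, variances)
    q = 0.0
    sw = 0.0
    sw2 = 0.0
    for x, v in zip(values, variances):
        w = 1.0 / v
        q += w * (x - est) ** 2
        sw += w
        sw2 += w * w
    df = len(values) - 1
    denom = sw - sw2 / sw
    if denom <= 0:
        return 0.0, q
    return max(0.0, (q - df) / denom), q


def oracle_random_pool(values, variances):
    tau2, _ = oracle_dl_tau2(values, variances)
    sw = 0.0
    swx = 0.0
    for x, v in zip(values, variances):
        w = 1.0 / (v + tau2)
        sw += w
        swx += w * x
    return swx / sw, math.sqrt(1.0 / sw)


def oracle_ols(xs, ys):
    """Simple linear regression y = a + b*x via the normal equations."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    det = n * sxx - sx * sx
    b = (n * sxy - sx * sy) / det
    a = (sy - b * sx) / n
    return a, b


def oracle_wls(xs, ys, ws):
    """Weighted linear regression with slope SE and two-sided t p-value."""
    sw = sum(ws)
    sx = sum(w * x for w, x in zip(ws, xs))
    sy = sum(w * y for w, y in zip(ws, ys))
    sxx = sum(w * x * x for w, x in zip(ws, xs))
    sxy = sum(w * x * y for w, x, y in zip(ws, xs, ys))
    det = sw * sxx - sx * sx
    b = (sw * sxy - sx * sy) / det
    a = (sy - b * sx) / sw
    n = len(xs)
    rss = sum(w * (y - a - b * x) ** 2 for w, x, y in zip(ws, xs, ys))
    sigma2 = rss / (n - 2)
    # var(b) = sigma2 * sw / det  (the [1,1] entry of sigma2 * (X'WX)^-1)
    se_b = math.sqrt(sigma2 * sw / det)
    t = b / se_b
    p = 2.0 * _t_sf(abs(t), n - 2)
    return a, b, se_b, p


def _t_sf(t, df):
    """Student-t upper tail by numerical integration of the density."""
    # integrate density from 0 to t with Simpson's rule, subtract from 1/2
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))

    def pdf(x):
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    n = 4000
    h = t / n
    acc = pdf(0.0) + pdf(t)
    for i in range(1, n):
        acc += (4.0 if i % 2 else 2.0) * pdf(i * h)
    integral = acc * h / 3.0
    return max(0.0, 0.5 - integral)


def oracle_ranks(values):
    """Average ranks (ties share the mean rank), 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def oracle_spearman(xs, ys):
    """Rank both variables then take Pearson's correlation of the ranks."""
    rx = oracle_ranks(list(xs))
    ry = oracle_ranks(list(ys))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def oracle_auc_fine(a, b, step=1e-6):
    """Trapezoid AUC of the summary ROC curve on a very fine grid."""
    n = int(round(1.0 / step))
    eps = 1e-12
    total = 0.0
    prev_f = 0.0
    prev_t = _curve(a, b, eps)
    for i in range(1, n + 1):
        f = i * step
        t = _curve(a, b, min(max(f, eps), 1 - eps))
        total += 0.5 * (t + prev_t) * (f - prev_f)
        prev_f, prev_t = f, t
    return total


def _curve(a, b, fpr):
    lf = math.log(fpr / (1.0 - fpr))
    lt = (a + (1.0 + b) * lf) / (1.0 - b)
    if lt >= 0:
        return 1.0 / (1.0 + math.exp(-lt))
    e = math.exp(lt)
    return e / (1.0 + e)
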