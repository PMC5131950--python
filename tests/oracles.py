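"""Independent textbook-formula oracles used to validate the pipeline's
statistics. Deliberately avoids scipy.stats test functions: t-tests are
assembled from explicit mean/variance formulas and the t survival
function is obtained by numerically integrating the t density."""

import math

from scipy.integrate import quad
from scipy.stats import studentized_range


def t_pdf(x: float, df: float) -> float:
    lognorm = math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
    return (
        math.exp(lognorm)
        / math.sqrt(df * math.pi)
        * (1.0 + x * x / df) ** (-(df + 1) / 2)
    )


def t_sf(x: float, df: float) -> float:
    val, _ = quad(t_pdf, x, math.inf, args=(df,), epsabs=1e-13, epsrel=1e-13)
    return val


def _moments(xs):
    n = len(xs)
    m = sum(xs) / n
    v = sum((x - m) ** 2 for x in xs) / (n - 1)
    return n, m, v


def welch_t(x, y):
    """Welch two-sample t-test from first principles: (t, df, two-sided p)."""
    n1, m1, v1 = _moments(list(x))
    n2, m2, v2 = _moments(list(y))
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df, 2.0 * t_sf(abs(t), df)


def student_t(x, y):
    """Pooled-variance two-sample t-test: (t, df, two-sided p)."""
    n1, m1, v1 = _moments(list(x))
    n2, m2, v2 = _moments(list(y))
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, df, 2.0 * t_sf(abs(t), df)


def tukey_hsd_p(groups):
    """Tukey HSD p-values for equal-n groups: {(i, j): p}.

    Classical construction: q = |mi - mj| / sqrt(MSE / n) referred to
    the studentized-range distribution with k groups and N - k df.
    """
    k = len(groups)
    ns = [len(g) for g in groups]
    assert len(set(ns)) == 1, "Tukey oracle requires equal n"
    n = ns[0]
    means = [sum(g) / n for g in groups]
    sse = sum(sum((x - m) ** 2 for x in g) for g, m in zip(groups, means))
    df = k * n - k
    mse = sse / df
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / math.sqrt(mse / n)
            out[(i, j)] = float(studentized_range.sf(q, k, df))
    return out


def ols_line(xs, ys):
    """Closed-form least squares: (slope, intercept, r_squared)."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    syy = sum((y - my) ** 2 for y in ys)
    slope = sxy / sxx
    r2 = sxy**2 / (sxx * syy)
    return slope, my - slope * mx, r2
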