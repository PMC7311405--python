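"""Independent brute-force formula implementations used as test oracles.

Everything here is computed directly from textbook definitions with plain
Python loops / explicit sums, independent of the library code paths it
checks.
"""

import math


def percentile_oracle(values, q):
    """Linear interpolation between closest ranks: r = 1 + (n-1) q / 100."""
    s = sorted(float(v) for v in values)
    n = len(s)
    r = 1.0 + (n - 1) * q / 100.0
    k = int(math.floor(r))
    if k >= n:
        return s[-1]
    frac = r - k
    return s[k - 1] + frac * (s[k] - s[k - 1])


def _central_moments(values):
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    return n, m2, m3, m4


def skewness_oracle(values):
    """Adjusted Fisher-Pearson standardized third moment."""
    n, m2, m3, _ = _central_moments([float(v) for v in values])
    g1 = m3 / m2**1.5
    return g1 * math.sqrt(n * (n - 1)) / (n - 2)


def kurtosis_oracle(values):
    """Sample-corrected excess kurtosis (normal -> 0)."""
    n, m2, _, m4 = _central_moments([float(v) for v in values])
    g2 = m4 / m2**2 - 3.0
    return ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))


def anova_f_oracle(groups):
    """Between/within mean-square ratio from the sum-of-squares decomposition."""
    groups = [[float(v) for v in g] for g in groups]
    allv = [v for g in groups for v in g]
    gm = sum(allv) / len(allv)
    k = len(groups)
    ssb = sum(len(g) * (sum(g) / len(g) - gm) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    return (ssb / (k - 1)) / (ssw / (len(allv) - k))


def pooled_t_oracle(a, b):
    """Textbook pooled-variance (Student) two-sample t statistic."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def pearson_r_oracle(x, y):
    """Product-moment correlation from the definition."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def icc_oracle(ratings):
    """ICC(2,1) from an explicit two-way mean-squares decomposition."""
    rows = [[float(v) for v in r] for r in ratings]
    n = len(rows)
    k = len(rows[0])
    gm = sum(v for r in rows for v in r) / (n * k)
    row_means = [sum(r) / k for r in rows]
    col_means = [sum(rows[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - gm) ** 2 for rm in row_means)
    ssc = n * sum((cm - gm) ** 2 for cm in col_means)
    sst = sum((v - gm) ** 2 for r in rows for v in r)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
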