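"""Independent naive transcription of the distance-correlation displays.

Deliberately written as literal per-entry loops over the defining formulas,
sharing no code with rbpnet.dcor, so the two routes check each other.
"""

import math


def naive_distance_matrix(x):
    n = len(x)
    return [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]


def naive_u_center(a):
    n = len(a)
    col_sums = [sum(a[s][j] for s in range(n)) for j in range(n)]
    row_sums = [sum(a[i][t] for t in range(n)) for i in range(n)]
    grand = sum(row_sums)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            out[i][j] = (a[i][j]
                         - col_sums[j] / (n - 2)
                         - row_sums[i] / (n - 2)
                         + grand / ((n - 1) * (n - 2)))
    return out


def naive_dcov(au, bu):
    n = len(au)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += au[i][j] * bu[j][i]  # trace(A_u B_u)
    return total / (n * (n - 3))


def naive_dcor(x, y):
    au = naive_u_center(naive_distance_matrix(list(x)))
    bu = naive_u_center(naive_distance_matrix(list(y)))
    cov = naive_dcov(au, bu)
    var_x = naive_dcov(au, au)
    var_y = naive_dcov(bu, bu)
    return cov / math.sqrt(var_x * var_y)


def naive_chisq_pvalue(r_d, n):
    """P(chi2_1 > n*r_d + 1) via the standard-normal tail identity."""
    arg = n * r_d + 1.0
    if arg < 0:
        return 1.0
    return math.erfc(math.sqrt(arg / 2.0))
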