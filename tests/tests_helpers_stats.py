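"""Independent direct-formula oracles for the statistical operations."""

import math

import numpy as np
from scipy import stats as sps


def pearson_oracle(x, y):
    """Covariance/sd formula plus the t transform for the two-sided p-value."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    r = max(min(cov / (sx * sy), 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return r, 2 * sps.t.sf(abs(t), n - 2)


def welch_oracle(a, b):
    """Textbook Welch statistic with Welch–Satterthwaite degrees of freedom."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * sps.t.sf(abs(t), df)
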