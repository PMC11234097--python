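"""Group comparisons of total fatty acid contents: pooled two-sample t-test
and classical one-way ANOVA.

The t-test uses the pooled (equal-variance) Student's form with
df = n_a + n_b - 2, matching the integer degrees of freedom conventional in
small balanced culture comparisons; p-values are two-tailed from the t and
F distributions.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def two_sample_ttest(a, b) -> dict:
    """Pooled-variance Student's t: {'t', 'df', 'p'} (two-tailed).

    Degenerate inputs: if both groups have zero variance and equal means the
    comparison is vacuous and raises; a single zero-variance group with the
    same mean as the other yields t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return {"t": 0.0, "df": df, "p": 1.0}
        raise ValueError("zero pooled variance with unequal means")
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": df, "p": float(p)}


def one_way_anova(groups: dict) -> dict:
    """Classical one-way ANOVA over a {label: values} mapping.

    Returns {'F', 'df_between', 'df_within', 'p'}.  Conventions: all values
    identical -> F = 0, p = 1; zero within-group variance with unequal group
    means -> F = inf, p = 0.
    """
    arrays = [np.asarray(v, dtype=float).ravel() for v in groups.values()]
    k = len(arrays)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = [x.size for x in arrays]
    if min(ns) < 1:
        raise ValueError("empty group")
    N = sum(ns)
    if N <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ssb = sum(n * (x.mean() - grand) ** 2 for n, x in zip(ns, arrays))
    ssw = sum(((x - x.mean()) ** 2).sum() for x in arrays)
    df_b, df_w = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            return {"F": 0.0, "df_between": df_b, "df_within": df_w, "p": 1.0}
        return {"F": math.inf, "df_between": df_b, "df_within": df_w, "p": 0.0}
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return {"F": float(F), "df_between": df_b, "df_within": df_w, "p": p}


def week_group(duration_days) -> np.ndarray:
    """Bin culture durations into whole weeks: floor(days / 7)."""
    return np.floor_divide(np.asarray(duration_days, dtype=float), 7.0).astype(int)


def grouped_values(values, labels) -> dict:
    """Assemble a {label: value-vector} mapping, dropping missing labels."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype="object")
    keep = np.array([lab is not None and lab == lab for lab in labels])
    out: dict = {}
    for lab in np.unique(labels[keep].astype(str)):
        out[lab] = values[keep][labels[keep].astype(str) == lab]
    return out
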