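"""Independent brute-force references for the descriptive statistics.

Deliberately written as plain Python loops over explicit formulas, kept
free of any code from the package so they can serve as oracles.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import expit


def bf_mean(values):
    vals = [v for v in values if not math.isnan(v)]
    return sum(vals) / len(vals) if vals else float("nan")

def bf_sd(values):
    vals = [v for v in values if not math.isnan(v)]
    n = len(vals)
    if n < 2:
        return float("nan")
    m = sum(vals) / n
    return math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1))

def bf_skew(values):
    vals = [v for v in values if not math.isnan(v)]
    n = len(vals)
    if n == 0:
        return float("nan")
    m = sum(vals) / n
    m2 = sum((v - m) ** 2 for v in vals) / n
    m3 = sum((v - m) ** 3 for v in vals) / n
    if m2 == 0:
        return float("nan")
    return m3 / m2**1.5

def bf_pairs(series):
    out = []
    for t in range(len(series) - 1):
        a, b = series[t], series[t + 1]
        if not math.isnan(a) and not math.isnan(b):
            out.append((a, b))
    return out

def bf_rmssd(series):
    pairs = bf_pairs(series)
    if not pairs:
        return float("nan")
    return math.sqrt(sum((b - a) ** 2 for a, b in pairs) / len(pairs))

def bf_ar1(series):
    pairs = bf_pairs(series)
    n = len(pairs)
    if n < 2:
        return float("nan")
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)

def bf_pearson(x, y):
    pairs = [(a, b) for a, b in zip(x, y) if not (math.isnan(a) or math.isnan(b))]
    n = len(pairs)
    if n < 3:
        return float("nan")
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)

def bf_missing_proportion(n_completed, t_max=84):
    return 1 - n_completed / t_max

def bf_initial_elevation(series, first=6):
    head = [v for v in series[:first] if not math.isnan(v)]
    tail = [v for v in series[first:] if not math.isnan(v)]
    if not head or not tail:
        return float("nan")
    return sum(head) / len(head) - sum(tail) / len(tail)


def random_series(rng, t_max=84, missing_rate=0.3):
    """A random unit-interval series with missing slots, for oracle checks."""
    s = rng.random(t_max)
    s[rng.random(t_max) < missing_rate] = np.nan
    return s


def simulate_zoib_stat_table(seed, n_per=60, n_items=14, scale_eff=0.6,
                             intercept=-0.8, valence_eff=-0.5, phi=10.0,
                             pi0=0.10, re_sd=0.3):
    """A StatTable drawn directly from the zoib group model (known truth).

    Participant and item random intercepts with SD ``re_sd`` on logit(mu);
    the scale effect ``scale_eff`` acts on logit(mu); each cell is 0 with
    probability ``pi0``, otherwise Beta(mu*phi, (1-mu)*phi).
    """
    rng = np.random.default_rng(seed)
    z_i = rng.normal(0, re_sd, n_items)
    rows = []
    for g, n in (("likert", n_per), ("vas", n_per)):
        s = 1.0 if g == "vas" else 0.0
        for p in range(n):
            zp = rng.normal(0, re_sd)
            for j in range(n_items):
                valence = "negative" if j >= n_items - 9 else "positive"
                v = 1.0 if valence == "negative" else -1.0
                mu = expit(intercept + scale_eff * s + valence_eff * v + zp + z_i[j])
                y = 0.0 if rng.random() < pi0 else rng.beta(mu * phi, (1 - mu) * phi)
                rows.append((f"{g}{p}", g, f"item{j}", valence, y))
    return pd.DataFrame(rows, columns=["participant_id", "group", "item", "valence", "wp_mean"])
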