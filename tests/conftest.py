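import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic experiment shared across read-only tests."""
    from eeseq import SimConfig, simulate_experiment
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture()
def toy_counts():
    from eeseq import ExpressionMatrix
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.negative_binomial(10, 0.02, size=(200, 5)).astype(float),
        index=[f"g{i:03d}" for i in range(200)], columns=list("ABCDE"))
    df.iloc[0, 0] = 50000.0  # spiked gene to make TMM non-trivial
    return ExpressionMatrix(df, "counts")


def brute_force_tmm(counts: pd.DataFrame, ref_col: str,
                    logratio_trim: float = 0.3,
                    sum_trim: float = 0.05) -> pd.Series:
    """Independent loop-based trimmed weighted mean of M-values.

    Deliberately written from the published definition with plain Python
    loops and sorting, as an oracle for the vectorised implementation:
    for each sample, M and A values against the reference over doubly
    positive genes, drop the most extreme 30% of M and 5% of A by rank,
    average the survivors weighted by the inverse asymptotic binomial
    variance, and centre the factors to log-mean zero.
    """
    import math

    lib = counts.sum(axis=0)
    factors = {}
    for col in counts.columns:
        if col == ref_col:
            factors[col] = 1.0
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in counts.index:
            y, yr = counts.loc[g, col], counts.loc[g, ref_col]
            if y > 0 and yr > 0:
                p, pr = y / lib[col], yr / lib[ref_col]
                m_vals.append(math.log2(p / pr))
                a_vals.append(0.5 * math.log2(p * pr))
                w_vals.append((lib[col] - y) / (lib[col] * y)
                              + (lib[ref_col] - yr) / (lib[ref_col] * yr))
        n = len(m_vals)
        if n == 0 or max(abs(m) for m in m_vals) < 1e-6:
            factors[col] = 1.0
            continue

        def ranks(vals):
            order = sorted(range(n), key=lambda i: vals[i])
            rk = [0.0] * n
            i = 0
            while i < n:
                j = i
                while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    rk[order[k]] = avg
                i = j + 1
            return rk

        rm, ra = ranks(m_vals), ranks(a_vals)
        lo_m = math.floor(n * logratio_trim) + 1
        lo_a = math.floor(n * sum_trim) + 1
        num = den = 0.0
        for i in range(n):
            if (lo_m <= rm[i] <= n + 1 - lo_m) and (lo_a <= ra[i] <= n + 1 - lo_a):
                num += m_vals[i] / w_vals[i]
                den += 1.0 / w_vals[i]
        factors[col] = 2.0 ** (num / den) if den else 1.0

    logs = [math.log(f) for f in factors.values()]
    centre = math.exp(sum(logs) / len(logs))
    return pd.Series({c: f / centre for c, f in factors.items()})
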