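"""Independent test oracles, deliberately implemented by routes different
from the package's own code paths."""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm


def dense_profile_area_ardi(
    lam: float, B: float, S0: float, n: int = 1_000_001
) -> tuple[float, float]:
    """Brute-force fine-grid area and half-mass position of B + S0*e^{-lam*s}.

    Trapezoid strips accumulated by cumsum, then linear search for the
    half-mass crossing; no package code involved.
    """
    s = np.linspace(0.0, 1.0, n)
    g = B + S0 * np.exp(-lam * s)
    ds = s[1] - s[0]
    strips = 0.5 * (g[:-1] + g[1:]) * ds
    cum = np.concatenate([[0.0], np.cumsum(strips)])
    total = cum[-1]
    half = 0.5 * total
    k = int(np.searchsorted(cum, half))
    frac = (half - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(total), float(s[k - 1] + frac * ds)


def pointwise_mean_sd_loop(profiles_values: list[np.ndarray]):
    """Naive per-point mean/sample-SD loops (oracle for ensemble_mean_sd)."""
    n = len(profiles_values)
    m = len(profiles_values[0])
    means, sds = np.empty(m), np.empty(m)
    for j in range(m):
        col = [profiles_values[i][j] for i in range(n)]
        mu = sum(col) / n
        means[j] = mu
        if n > 1:
            sds[j] = math.sqrt(sum((x - mu) ** 2 for x in col) / (n - 1))
        else:
            sds[j] = 0.0
    return means, sds


def studentized_range_cdf(q: float, k: int, df: int, n_nodes: int = 160) -> float:
    """CDF of the studentized range by direct double numerical integration.

    P(Q <= q) = ∫_0^∞ f_S(u) * P(range of k std normals <= q*u) du, where
    S = sqrt(chi2_df / df) and
    P(range <= w) = k ∫ φ(z) [Φ(z) − Φ(z−w)]^{k−1} dz.

    Both integrals use tensorized Gauss–Legendre quadrature; the
    integrands are smooth and effectively supported on |z| <= 9 (the
    φ(z) factor) and u in (0, 6] (the scaled-chi density), so fixed-order
    rules converge far below the 1e−6 comparison tolerance.
    """
    if q <= 0:
        return 0.0
    xz, wz = np.polynomial.legendre.leggauss(n_nodes)
    z = 0.5 * (xz + 1.0) * 18.0 - 9.0  # [-9, 9]
    wz = wz * 9.0
    xu, wu = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (xu + 1.0) * 6.0  # (0, 6]
    wu = wu * 3.0

    log_c = (df / 2.0) * math.log(df / 2.0) - math.lgamma(df / 2.0)
    with np.errstate(divide="ignore"):
        f_s = 2.0 * np.exp(log_c + (df - 1) * np.log(u) - df * u * u / 2.0)
    f_s = np.nan_to_num(f_s)

    w_mat = q * u  # (n,)
    inner = norm.cdf(z)[None, :] - norm.cdf(z[None, :] - w_mat[:, None])
    p_range = k * np.sum(
        norm.pdf(z)[None, :] * np.clip(inner, 0.0, None) ** (k - 1) * wz[None, :],
        axis=1,
    )
    val = float(np.sum(f_s * p_range * wu))
    return min(val, 1.0)


def tukey_pvalues_from_scratch(samples: list[np.ndarray]) -> dict:
    """Tukey HSD p-values for equal-sized groups via the studentized-range
    CDF above; keyed by group index pairs (i, j)."""
    k = len(samples)
    n = len(samples[0])
    assert all(len(s) == n for s in samples), "oracle assumes equal group sizes"
    means = [float(np.mean(s)) for s in samples]
    df = k * (n - 1)
    mse = sum(float(np.sum((np.asarray(s) - m) ** 2)) for s, m in zip(samples, means)) / df
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            q_obs = abs(means[i] - means[j]) / math.sqrt(mse / n)
            out[(i, j)] = 1.0 - studentized_range_cdf(q_obs, k, df)
    return out


def two_way_ss_partition(values, a_labels, b_labels):
    """Naive balanced two-way ANOVA sum-of-squares partition.

    Returns (SS_A, SS_B, SS_AB, SS_E) by direct cell-mean arithmetic.
    """
    values = np.asarray(values, dtype=float)
    a_labels = np.asarray(a_labels)
    b_labels = np.asarray(b_labels)
    A = sorted(set(a_labels.tolist()))
    Bs = sorted(set(b_labels.tolist()))
    grand = values.mean()
    n_cell = len(values) / (len(A) * len(Bs))
    ss_a = ss_b = ss_ab = ss_e = 0.0
    for a in A:
        ma = values[a_labels == a].mean()
        ss_a += (a_labels == a).sum() * (ma - grand) ** 2
    for b in Bs:
        mb = values[b_labels == b].mean()
        ss_b += (b_labels == b).sum() * (mb - grand) ** 2
    for a in A:
        for b in Bs:
            mask = (a_labels == a) & (b_labels == b)
            cell = values[mask]
            mab = cell.mean()
            ma = values[a_labels == a].mean()
            mb = values[b_labels == b].mean()
            ss_ab += n_cell * (mab - ma - mb + grand) ** 2
            ss_e += float(np.sum((cell - mab) ** 2))
    return ss_a, ss_b, ss_ab, ss_e
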