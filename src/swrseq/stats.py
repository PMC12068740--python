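"""The two one-sided significance procedures shared by the pipeline.

Both tests report an upper-tail p-value, ``p = 1 - Phi(z)``: only enrichment is
biologically tested. No multiple-testing correction is applied; downstream
callers report raw per-site p-values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm

__all__ = ["ZTestResult", "one_sample_ztest", "proportion_ztest"]


@dataclasses.dataclass(frozen=True)
class ZTestResult:
    """Result of a one-sided (upper tail) Z-test.

    ``mu``/``sigma`` hold the empirical noise-model parameters for the
    one-sample test; for the proportion test ``mu`` is the baseline proportion
    and ``sigma`` the standard error of the estimate under the null.
    """

    statistic: float
    p_value: float
    mu: float
    sigma: float
    n: int


def one_sample_ztest(x: float, noise: np.ndarray) -> ZTestResult:
    """Test whether ``x`` exceeds an empirical noise distribution.

    The noise vector supplies the null: ``z = (x - mean(noise)) / sd(noise)``
    with the sample standard deviation (denominator ``n - 1``), and
    ``p = 1 - Phi(z)``.

    Parameters
    ----------
    x : observed signal value.
    noise : vector of >= 2 noise observations with positive variance.
    """
    noise = np.asarray(noise, dtype=float)
    if noise.size < 2:
        raise ValueError("noise model requires at least 2 observations")
    mu = float(noise.mean())
    sigma = float(noise.std(ddof=1))
    if sigma == 0:
        raise ValueError("noise model has zero variance")
    z = (x - mu) / sigma
    return ZTestResult(statistic=z, p_value=float(norm.sf(z)), mu=mu, sigma=sigma, n=noise.size)


def proportion_ztest(hits: int, n: int, p0: float) -> ZTestResult:
    """One-sample proportion Z-test of ``hits/n`` against baseline ``p0``.

    ``SE = sqrt(p0 (1 - p0) / n)``; ``z = (hits/n - p0) / SE``; upper-tail p.
    No continuity correction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= hits <= n:
        raise ValueError("hits must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("baseline proportion must lie in (0, 1)")
    p_hat = hits / n
    se = float(np.sqrt(p0 * (1 - p0) / n))
    z = (p_hat - p0) / se
    return ZTestResult(statistic=z, p_value=float(norm.sf(z)), mu=p0, sigma=se, n=n)
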