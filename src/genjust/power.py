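"""Noncentral-F power analysis for one-group repeated-measures ANOVA.

Follows the G*Power "repeated measures, within factors" parameterization:
with effect size f (f^2 = eta_p^2 / (1 - eta_p^2)), N subjects, m repeated
measurements, correlation among repeated measures rho and nonsphericity
correction epsilon,

    lambda = f^2 * N * m * epsilon / (1 - rho)
    df1    = (m - 1) * epsilon
    df2    = (N - 1) * (m - 1) * epsilon
    power  = P( F'(df1, df2, lambda) > F_crit(alpha, df1, df2) ).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

MAX_N = 10_000_000


@dataclass(frozen=True)
class PowerResult:
    f: float
    lam: float
    df1: float
    df2: float
    critical_F: float
    power: float


def eta2_to_f(eta_p2: float) -> float:
    """Cohen's f from partial eta squared: f = sqrt(eta / (1 - eta))."""
    if not 0 <= eta_p2 < 1:
        raise ValueError("eta_p2 must lie in [0, 1)")
    return (eta_p2 / (1 - eta_p2)) ** 0.5


def _validate(n: int, m: int, rho: float, eps: float, alpha: float) -> None:
    if n < 2:
        raise ValueError("n must be >= 2")
    if m < 2:
        raise ValueError("m must be >= 2")
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    if not 0 < eps <= 1:
        raise ValueError("eps must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")


def achieved_power(eta_p2: float | None = None, *, f: float | None = None,
                   n: int, m: int, rho: float = 0.0, eps: float = 1.0,
                   alpha: float = 0.05) -> PowerResult:
    """Post-hoc power of the repeated-measures within-factors F-test."""
    _validate(n, m, rho, eps, alpha)
    if (eta_p2 is None) == (f is None):
        raise ValueError("give exactly one of eta_p2 or f")
    if f is None:
        f = eta2_to_f(eta_p2)
    if f < 0:
        raise ValueError("f must be >= 0")
    lam = f * f * n * m * eps / (1 - rho)
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    fcrit = float(stats.f.isf(alpha, df1, df2))
    power = float(stats.ncf.sf(fcrit, df1, df2, lam)) if lam > 0 \
        else float(stats.f.sf(fcrit, df1, df2))
    return PowerResult(f=f, lam=lam, df1=df1, df2=df2, critical_F=fcrit,
                       power=power)


def required_n(eta_p2: float | None = None, *, f: float | None = None,
               target_power: float, m: int, rho: float = 0.0, eps: float = 1.0,
               alpha: float = 0.05) -> int:
    """Smallest N whose achieved power reaches ``target_power``.

    Power is strictly increasing in N, so a doubling bracket followed by
    bisection finds the exact minimal integer.
    """
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")

    def pw(n: int) -> float:
        return achieved_power(eta_p2, f=f, n=n, m=m, rho=rho, eps=eps,
                              alpha=alpha).power

    lo, hi = 2, 2
    while pw(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > MAX_N:
            raise ValueError(f"no N <= {MAX_N} reaches power {target_power}")
    while lo < hi:
        mid = (lo + hi) // 2
        if pw(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo
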