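"""A-priori and post-hoc power for the repeated-measures within-factors F-test.

The a-priori computation asks: with a dangerousness effect of partial
eta^2 = .035 (two measurement levels, repeated-measure correlation set
conservatively to 0, no sphericity correction), how many participants give
90% power at alpha = .05?  The post-hoc computations report the power the
achieved samples had for the observed dangerousness effect sizes.
"""

from genjust import achieved_power, required_n

n = required_n(0.035, target_power=0.90, m=2, rho=0.0, eps=1.0, alpha=0.05)
print(f"a-priori required sample size: N = {n}")

for eta, size in ((0.018, 175), (0.021, 233)):
    res = achieved_power(eta, n=size, m=2, rho=0.0, eps=1.0, alpha=0.05)
    print(f"post hoc: eta_p^2 = {eta}, N = {size} -> "
          f"f = {res.f:.3f}, lambda = {res.lam:.2f}, "
          f"power = {res.power:.2f}")
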