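"""Convergence diagnostics and highest-density intervals by hand.

PSRF (Gelman-Rubin) compares between- to within-chain variance; ESS
discounts draws by their autocorrelation; the HDI is the shortest interval
holding a given posterior mass (narrower than the equal-tailed interval
for skewed posteriors).
"""

import numpy as np

from nestpool import effective_sample_size, gelman_rubin, hdi

# two tiny chains you can check with pencil and paper
same = np.array([[1.0, 2, 3, 4], [1, 2, 3, 4]])
shifted = np.array([[1.0, 2, 3, 4], [2, 3, 4, 5]])
print(f"PSRF identical chains: {gelman_rubin(same)[0]:.4f}   (sqrt(0.75) = {np.sqrt(0.75):.4f})")
print(f"PSRF shifted chains:   {gelman_rubin(shifted)[0]:.4f}   (sqrt(1.05) = {np.sqrt(1.05):.4f})")

rng = np.random.default_rng(0)
iid = rng.normal(size=(1, 10_000))
print(f"\nESS of 10,000 iid draws: {effective_sample_size(iid)[0]:.0f}")
rho, n = 0.9, 10_000
x = np.empty(n); x[0] = rng.normal()
for i in range(1, n):
    x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * rng.normal()
print(f"ESS of AR(1) rho=0.9:    {effective_sample_size(x[None, :])[0]:.0f} "
      f"(theory n(1-rho)/(1+rho) = {n * (1 - rho) / (1 + rho):.0f})")

skewed = rng.gamma(2.0, 1.0, 20_000)
lo, hi = hdi(skewed, 0.95)
eq = np.quantile(skewed, [0.025, 0.975])
print(f"\nGamma(2,1) draws: 95% HDI [{lo:.2f}, {hi:.2f}] width {hi - lo:.2f}; "
      f"equal-tailed [{eq[0]:.2f}, {eq[1]:.2f}] width {eq[1] - eq[0]:.2f}")
print("the HDI hugs the mode of a skewed posterior; equal tails waste width on the right")
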