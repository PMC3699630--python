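"""Model random-constellation performance with a beta distribution.

Scores 100 random 10-sensor constellations with the full chain, fits
Beta(alpha, beta) to their balanced accuracies, and asks: how many random
draws would be needed to match the constellation found by virtual-space SSNR
elimination?
"""

import numpy as np

from erpselect import (
    ChainConfig, clamp_accuracies, epoch, exceedance, expected_random_draws,
    fit_beta, random_constellation_accuracies, run_chain,
    select_constellations, simulate_session,
)
from erpselect.benchmarks import benchmark_config

cfg = benchmark_config(seed=2)
runs = simulate_session(cfg, 0, 0)

_, accs = random_constellation_accuracies(runs, size=10, n=100, seed=2)
fit = fit_beta(clamp_accuracies(accs), size=10)
print(f"100 random 10-of-32 constellations: "
      f"mean bACC {accs.mean():.3f}, range [{accs.min():.3f}, {accs.max():.3f}]")
print(f"beta fit: alpha={fit.alpha:.1f}, beta={fit.beta:.1f} "
      f"(mean {fit.mean:.3f})")

sets = select_constellations("ssnr_v", runs[0], [10], ChainConfig())
train, test = [epoch(r, (0.0, 1000.0)) for r in runs]
selected_bacc = run_chain(train, test, sets[10])
p = exceedance(fit, selected_bacc)
print(f"\nselected constellation bACC: {selected_bacc:.3f}")
print(f"P(random constellation >= that): {p:.2e}")
draws = expected_random_draws(fit, selected_bacc)
print(f"expected random draws to match it: "
      f"{'inf' if np.isinf(draws) else f'{draws:.0f}'}")
print("-> informed selection is worth that many blind guesses.")
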