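"""Positional autocorrelation of a log2-ratio profile vs a permutation null.

Neighboring genes share expression shifts (segmental effects), so the
chromosome-ordered log2 ratios are positively autocorrelated at short
lags — the signal that motivates a hidden Markov model along the gene
order.  Shuffling the gene order destroys it.
"""

import pairhmm as ph

params = ph.default_generative_parameters()
profile, _ = ph.simulate_hmm_profile(params, {"1": 1500, "2": 1500}, seed=7)

null = ph.permutation_null(profile, max_lag=5, n_perm=500, seed=8)
print("lag  observed_acf  null_mean  null_sd  p")
for lag, obs, mu, sd, p in zip(null.lags, null.observed, null.null_mean,
                               null.null_sd, null.pvalues):
    print(f"{lag:>3}  {obs:>12.3f}  {mu:>9.3f}  {sd:>7.3f}  {p:.4f}")
print("Observed short-lag autocorrelation far exceeds the shuffled-order "
      "null (empirical p = 1/(n_perm+1) is the smallest attainable value).")
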