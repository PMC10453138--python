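"""Absolute quantification of one ddPCR well.

Simulates a 20,000-droplet well at a known concentration, calls each
droplet positive/negative from its fluorescence amplitude, and converts
the negative fraction into copies via Poisson statistics.
"""

from herbauth import DropletSimParams, call_droplets, estimate_lambda, simulate_droplets

lam_true = 0.25  # copies per droplet
ds = simulate_droplets(DropletSimParams(lambda_true=lam_true, seed=11))
call = call_droplets(ds)
est = estimate_lambda(call)

print(f"droplets: {call.n_total}  positive: {call.n_positive}  "
      f"negative: {call.n_negative}")
print(f"threshold amplitude: {call.threshold:.0f}")
print(f"lambda-hat: {est.lambda_hat:.4f} copies/droplet "
      f"(true {lam_true}), 95% CI [{est.ci_low:.4f}, {est.ci_high:.4f}]")
print(f"copies per reaction: {est.copies_per_reaction:.0f}")
print(f"copies per microlitre: {est.copies_per_ul:.0f}")
# The negative-droplet fraction e^(-lambda) carries all the information:
# lambda-hat = -ln(n_neg / n_total), so the estimate needs no standard curve.
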