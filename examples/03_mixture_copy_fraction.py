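"""Quantifying an adulterant: copy% and mass% of olive leaf in oregano.

Builds a gravimetric 5% (m/m) olive-in-oregano mixture, simulates both
species' ddPCR assays, and recovers the adulterant share as a
genome-corrected copy percentage and a DNA-mass percentage.
"""

from herbauth import (DropletSimParams, MixtureSpec, SpeciesAssay,
                      call_droplets, copy_fraction, estimate_lambda,
                      mass_fraction, simulate_droplets, simulate_mixture_copies)

assays = {
    "Olea europaea": SpeciesAssay("Olea europaea", genome_size_1c_pg=1.42,
                                  class_label="adulterant"),
    "Origanum vulgare": SpeciesAssay("Origanum vulgare", genome_size_1c_pg=0.96,
                                     class_label="ingredient"),
}
spec = MixtureSpec(components=(("Olea europaea", 0.05),
                               ("Origanum vulgare", 0.95)),
                   total_template_mass_ng=18.0)
true_copies = simulate_mixture_copies(spec, assays)
print("true target copies:",
      {k: round(v) for k, v in true_copies.items()})

estimates = {}
for i, (species, copies) in enumerate(true_copies.items()):
    ds = simulate_droplets(DropletSimParams(lambda_true=copies / 20_000,
                                            n_droplets=20_000, seed=20 + i))
    estimates[species] = estimate_lambda(call_droplets(ds))

cf = copy_fraction(estimates["Olea europaea"], estimates["Origanum vulgare"],
                   assays["Olea europaea"], assays["Origanum vulgare"])
mp = mass_fraction(cf, assays["Olea europaea"], assays["Origanum vulgare"])
print(f"olive copy%: {cf.copy_pct:.2f}  (genome equivalents "
      f"{cf.ge_adulterant:.0f} vs {cf.ge_ingredient:.0f})")
print(f"olive DNA mass%: {mp:.2f}  (gravimetric truth: 5.00)")
# copy% is below mass% here because the olive genome (1.42 pg/1C) is larger
# than oregano's (0.96): the same mass holds fewer olive genome copies.
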