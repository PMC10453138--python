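"""The DNA accounting purity screen.

Compares the ddPCR-measured copies of the declared species against the
copies expected if all fluorometrically measured DNA mass belonged to
it.  A pure sample lands inside the expected range; a sample whose DNA
is half foreign falls clearly below it.
"""

import math

from herbauth import (DropletSimParams, SpeciesAssay, account, call_droplets,
                      estimate_lambda, expected_range, simulate_droplets,
                      simulate_fluorometry)
from herbauth.accounting import expected_copies

assay = SpeciesAssay("Origanum vulgare", genome_size_1c_pg=0.96,
                     class_label="ingredient")
mass_ng = 18.0
n_droplets = 20_000

for name, purity in (("pure oregano", 1.0), ("50% foreign DNA", 0.5)):
    fluoro = simulate_fluorometry(mass_ng / 1.8, cv=0.05, seed=3)
    rng = expected_range(fluoro.mean * 1.8, fluoro.sd * 1.8, assay, k=2.0)
    lam = purity * expected_copies(mass_ng, assay) / n_droplets
    ds = simulate_droplets(DropletSimParams(lambda_true=lam,
                                            n_droplets=n_droplets, seed=7))
    result = account(estimate_lambda(call_droplets(ds)), rng)
    print(f"{name}: measured {result.measured_copies:,.0f} copies, "
          f"expected [{result.expected_low:,.0f}, {result.expected_high:,.0f}] "
          f"-> ratio {result.ratio:.2f}, flag {result.flag}")
# ratio ~ the fraction of the DNA mass actually belonging to the declared
# species; "below" is the screen's signal for dilution by foreign material.
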