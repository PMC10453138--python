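"""The full authentication pipeline on a self-contained demo cohort.

Writes a demo bundle (pure oregano samples, olive-spiked samples at
2/5/10% m/m, a multi-species quality-control blend, and its packaged
read-count fixture), then runs screen -> classify -> quantify ->
concordance and prints the key result tables.
"""

from pathlib import Path

from herbauth import load_config, make_demo, run_pipeline

outdir = Path("scratch/demo")
cfg_path = make_demo(outdir, seed=1)
result = run_pipeline(load_config(cfg_path))

print("== DNA accounting screen ==")
print(result.accounting[["sample", "measured_copies", "expected_low",
                         "expected_high", "ratio", "flag"]]
      .round({"measured_copies": 0, "expected_low": 0, "expected_high": 0,
              "ratio": 2}).to_string(index=False))

print("\n== ddPCR quantification of flagged taxa ==")
q = result.quantification
print(q[["sample", "taxon", "read_pct", "copy_pct", "mass_pct", "status"]]
      .round(2).to_string(index=False))

print("\n== read% vs copy% concordance ==")
print(result.concordance.round(3).to_string(index=False))
print(f"\nfull result bundle: {result.outdir}")
# The spiked samples show mass% tracking the gravimetric series while
# read% stays compressed; the pure samples trigger no quantification and
# pass the accounting screen.
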