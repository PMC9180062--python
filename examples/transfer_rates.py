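"""Brewing transfer rates: from single-sample algebra to survey summaries.

Shows the leaf->infusion mass-balance arithmetic for Pb, then recovers
the configured per-element mean transfer rates from a simulated paired
survey of 91 samples.
"""

from tearisk import (
    DEFAULT_BREWING,
    ConcentrationDataset,
    infusion_concentration,
    mean_transfer_rates,
    transfer_rate,
)
from tearisk.synthetic import default_sim_specs, gen_infusions, gen_made_tea

# one sample: mean leaf Pb at the mean transfer rate
c_i = infusion_concentration(0.84, 0.315, DEFAULT_BREWING)
print(f"Pb: 0.84 mg/kg leaf at T=31.5% -> infusion {c_i:.2f} ug/L "
      f"({c_i / 1000:.4f} mg/L; drinking-water limit 0.01 mg/L)")
print(f"   round trip: T = {transfer_rate(c_i, 0.84, DEFAULT_BREWING):.3f}")

# a paired 91-sample survey
specs = [s.model_copy(update={"nd_fraction": 0.0}) for s in default_sim_specs()]
made = gen_made_tea(specs, n=91, seed=42)
infusions = gen_infusions(made, specs, seed=43)
combined = ConcentrationDataset(list(made) + list(infusions), made.brewing)
print("\nPer-element mean transfer rate over 91 simulated samples:")
print(mean_transfer_rates(combined).round(3))
print(
    "\nmean_t is the arithmetic mean of per-sample release fractions; Ni is\n"
    "the most extractable element (~70%), Cu the least (~10%)."
)
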