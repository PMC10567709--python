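"""Draw a calibrated synthetic emission-factor sample and summarize it.

Emission factors (CH4 release per gram of termite per hour) observed in
the field are strongly right-skewed.  The generator draws from a
zero-inflated truncated lognormal moment-matched to the observational
summary: mean 3.81, s.d. 4.10, range 0.0-25.26 ug CH4 g^-1 h^-1.
"""

from termiteflux import EFGeneratorConfig, gen_ef_sample, ef_summary

sample = gen_ef_sample(EFGeneratorConfig(n=50_000, seed=42))
s = ef_summary(sample)

print(f"n        : {len(sample)}")
print(f"mean     : {s.mean:.3f}  (target 3.81 ug CH4 g^-1 h^-1)")
print(f"s.d.     : {s.sd:.3f}  (target 4.10)")
print(f"range    : {s.min:.2f} - {s.max:.2f}  (bounds 0.0 - 25.26)")
print()
print("The sample feeds the Monte-Carlo ensemble: each member draws one")
print("factor per land-cover class, so the skew of this distribution is")
print("what drives the spread of the global emission total.")
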