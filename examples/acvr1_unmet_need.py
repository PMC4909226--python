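"""Size the ACVR1-mutant patient population: FOP plus pediatric high-grade glioma.

FOP (fibrodysplasia ossificans progressiva) is caused by activating ACVR1
mutations and occurs in ~1 in 2 million people per year; the same kinase
mutations are reported in 20-30% of pediatric high-grade gliomas.  Summing the
annual incidence intervals bounds the patient population a therapy against
mutant ACVR1 could serve.
"""

from varlap.epi import acvr1_example_indications, annual_cases, cumulative_incidence

indications = acvr1_example_indications()
for ind in indications:
    lo, hi = annual_cases(ind)
    print(f"{ind.name:>14}: {lo:7.1f} - {hi:7.1f} mutation-positive cases / year (US)")
lo, hi = cumulative_incidence(indications)
print(f"{'cumulative':>14}: {lo:7.1f} - {hi:7.1f}")
print(f"\nEven at the upper bound ({hi:.0f}), fewer than 500 US patients per year —")
print("an orphan-scale population until endometrial-cancer carriers are added.")
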