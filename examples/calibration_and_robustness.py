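"""Check the null model's operating characteristics on background-only data.

On data where every match is pure chance (planted at exactly the
burden-proportional rate), nominal p-values should be conservative-or-uniform,
the full hit filter should call nothing, and p should not track protein
length once burden is modeled.
"""

from varlap import analyze, generate_null_dataset
from varlap.simulate import robustness_report

dataset = generate_null_dataset(1000, gamma_true=10.0, seed=42)
out = analyze(dataset.somatic, dataset.disease, dataset.proteome, dataset.expression, seed=42)

frac = (out.frame["p"] < 0.05).mean()
rep = robustness_report(out.frame)

print(f"fraction of genes with nominal p < 0.05: {frac:.3f} (<= 0.05 means conservative)")
print(f"hits after the full filter: {len(out.hits)} (background-only data)")
print(f"Spearman rho(p, protein length) = {rep.rho_length:+.3f} "
      f"[{rep.rho_length_ci[0]:+.3f}, {rep.rho_length_ci[1]:+.3f}]")
print(f"Spearman rho(p, mutation burden) = {rep.rho_burden:+.3f}")
print("Near-zero length correlation shows the burden-scaled null removes the")
print("long-gene bias; the mild negative burden correlation reflects the")
print("discrete null's extra conservatism for sparsely mutated genes.")
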