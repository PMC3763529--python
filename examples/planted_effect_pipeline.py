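"""Full pipeline on a synthetic genome with a planted selection effect.

Plants observed mutations whose |dMFE| quantile follows Beta(1, theta):
theta=2 for essential genes biases their observed mutations toward
structure preservation (theoretical median percentile
100*(1-0.5**(1/2)) = 29.3%), theta=1 leaves nonessential genes at the
null (median 50%).  The pipeline should recover those medians and a
small Mann-Whitney P.
"""

from foldsel import render_summary_tables
from foldsel.pipeline import analyze
from foldsel.synthetic import (SyntheticConfig, generate_catalog,
                               plant_observed_mutations)

cfg = SyntheticConfig(n_genes=450, min_codons=20, max_codons=45, cap=50,
                      theta_essential=2.0, theta_nonessential=1.0, seed=401)
catalog, labels = generate_catalog(cfg)
snps, truth = plant_observed_mutations(catalog, labels, cfg)
print(f"{len(catalog)} genes, planted mutations in {len(truth)} genes "
      f"({len(snps)} SNPs)")

rows = [(s.position, s.ref, s.alt) for s in snps]
result = analyze(catalog, rows, labels=labels, cap=cfg.cap, seed=cfg.seed,
                 ties="midrank")
print(render_summary_tables(result["summary"]))
print("Essential genes show a lower median percentile than nonessential")
print("ones when the planted constraint (theta=2) is active: their")
print("observed mutations perturb the mRNA structure less than random")
print("synonymous mutations would.")
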