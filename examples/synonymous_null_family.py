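"""Build a gene's synonymous null family and its |dMFE| percentile.

For a gene observed with one point mutation, the null model is the set
of all (or up to 1000 sampled) single synonymous mutants.  The
percentile of the observed |dMFE| within the family measures how
structure-preserving the observed mutation is: small percentile =
unusually mild structural effect.
"""

import numpy as np

from foldsel import (FoldingConfig, abs_delta_mfe, build_mutant_family,
                     fold_mfe_many, percentile_for_gene, ts_tv_ratio)
from foldsel.synmut import apply_substitutions

cds = ("ATGGCTGGTCACGAACTGCTGAAAGGTGGCCTGATCGTTGCTGCACGTTCT"
       "GGTGAAGATCTGCCGCAGTTCGCTCACTAA")
fam = build_mutant_family(cds, k=1, cap=1000, seed=0, gene_id="demo")
print(f"family: {fam.size} members, mode={fam.mode}")
print(f"family ts/tv ratio: "
      f"{ts_tv_ratio([(cds[p], a) for m in fam.members for p, a in m]):.2f}")

cfg = FoldingConfig()
ancestor = fold_mfe_many([cds], cfg)[0]
members = fold_mfe_many(fam.mutated_sequences(cds), cfg)
deltas = [abs_delta_mfe(ancestor, m).abs for m in members]

# take one family member as the "observed" mutation
observed = apply_substitutions(cds, fam.members[17])
obs_delta = abs_delta_mfe(ancestor, fold_mfe_many([observed], cfg)[0])
pct = percentile_for_gene(obs_delta.abs, deltas)
pct_mid = percentile_for_gene(obs_delta.abs, deltas, ties="midrank")

print(f"ancestor MFE = {ancestor.value:.1f}, observed |dMFE| = "
      f"{obs_delta.abs:.1f}")
print(f"percentile (strict) = {pct:.3f}, (midrank) = {pct_mid:.3f}")
print(f"median family |dMFE| = {np.median(deltas):.2f}")
print()
print("A percentile of e.g. 0.30 means the observed mutation changes the")
print("MFE more than 30% of random synonymous mutations would.")
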