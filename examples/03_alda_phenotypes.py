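"""Derive lithium-response phenotypes from Alda-scale scores.

Total = max(0, A - sum(B)); good responder iff total >= 7; the continuous
trait is the A score, dropping subjects whose B total exceeds 4.
"""

from mirwin import gen_alda_scores
from mirwin.phenotype import derive_phenotypes

scores = gen_alda_scores(n_subjects=2_563, seed=14)
pheno = derive_phenotypes(scores)

n_good = (pheno["responder"] == "good").sum()
n_excl = pheno["excluded_continuous"].sum()
print(f"{len(pheno)} subjects")
print(f"good responders (total >= 7): {n_good} ({n_good / len(pheno):.1%})")
print(f"excluded from continuous trait (sum B > 4): {n_excl}")
print(f"continuous trait mean A among eligible: "
      f"{pheno['continuous'].dropna().mean():.2f}")
print(pheno.head(5).to_string(index=False))
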