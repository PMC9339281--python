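"""Enrichment and feature-shift statistics for a protein set.

Compares a synthetic RLBP-like set against a background proteome: Fisher
exact tests on domain-count bins ({0, 1, 2, >=3} domains), and two-sided
Mann-Whitney tests (Bonferroni-corrected) on descriptor distributions.
"""

import numpy as np

import rlooppred as rp

rng = np.random.default_rng(3)

# RLBP-like proteins carry more domains (Poisson mean 3 vs 1)
set_domains = rng.poisson(3.0, 150)
bg_domains = rng.poisson(1.0, 2000)
print("domain-count enrichment (set vs background):")
for bin_label, res in rp.domain_count_classes(
        set_domains, bg_domains, correction="bonferroni").items():
    f = res["fisher"]
    print(f"  {bin_label:>3} domains: {res['set_proportion']:.2f} vs "
          f"{res['background_proportion']:.2f}  adj-p = {f.adjusted_p:.2e}")

# descriptor shifts: disorder up, GRAVY down in the RLBP-like set
set_disorder = rng.normal(45, 12, 150)
bg_disorder = rng.normal(30, 12, 2000)
set_gravy = rng.normal(-0.6, 0.3, 150)
bg_gravy = rng.normal(-0.3, 0.3, 2000)
print("\nfeature-distribution shifts (Mann-Whitney, Bonferroni m=2):")
for name, a, b in [("disorder %", set_disorder, bg_disorder),
                   ("GRAVY", set_gravy, bg_gravy)]:
    cmp = rp.mannwhitney_compare(a, b, n_comparisons=2)
    arrow = {1: "higher", -1: "lower", 0: "equal"}[cmp.direction]
    print(f"  {name:>10}: set median {arrow}, U = {cmp.u_statistic:.0f}, "
          f"adj-p = {cmp.adjusted_p:.2e}")
print("\nThe >=3-domain bin and both descriptor shifts are strongly "
      "enriched, the pattern expected of multivalent R-loop binders.")
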