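"""Case-control contrast on regional MS with covariate adjustment.

Fits, per region, MS ~ group + age + sex + age x sex, extracts the group
t-statistic (user - control), corrects with BH-FDR across 308 regions,
and aggregates to Yeo-7 networks. Also shows the TIV replication check.
"""

import numpy as np

from msntools import (
    cohort_strengths,
    compare_global_ms,
    draw_regional_profile,
    fit_regional_contrast,
    jaccard_flags,
    make_effect_map,
    make_parcellation,
    network_contrast,
    simulate_morphometry,
)

parc = make_parcellation(308, 152, seed=1)
profile = draw_regional_profile(parc, seed=2)
effect = make_effect_map(parc, 20, seed=3, profile=profile)
table, truth = simulate_morphometry(
    parc, 24, effect_map=effect, effect_scale=2.5, seed=4, profile=profile,
    covariate_model={"tiv": True},
)
strengths = cohort_strengths(table)

glob = compare_global_ms(strengths, table.subjects)
print(f"global: Welch t = {glob['t']:.2f} (p = {glob['p_t']:.2g}), "
      f"KS = {glob['ks_statistic']:.3f} (p = {glob['p_ks']:.2g})")

sm = fit_regional_contrast(strengths, table.subjects)
hits = np.flatnonzero(sm.significant)
overlap = len(set(hits) & set(truth.affected_regions))
print(f"regional: {len(hits)}/308 FDR-significant; {overlap}/20 planted regions recovered")

nets = network_contrast(strengths, table.subjects, parc, atlas="yeo7")
top = nets.loc[nets.p_fdr.idxmin()]
print(f"network (Yeo-7): strongest contrast in {top.label} "
      f"(t = {top.t:.2f}, p_fdr = {top.p_fdr:.3g})")

sm_tiv = fit_regional_contrast(strengths, table.subjects, extra_covariates=("tiv",))
j = jaccard_flags(sm.significant, sm_tiv.significant)
print(f"TIV replication: Jaccard overlap of flagged regions = {j:.2f}, "
      f"t-map correlation = {np.corrcoef(sm.t, sm_tiv.t)[0, 1]:.3f}")
# A Jaccard near 1 means head-size adjustment barely changes which regions
# are flagged - the contrast is robust to the TIV nuisance.
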