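"""Generate a synthetic acute right-hemisphere stroke cohort and summarise it.

Prints the cohort-level descriptives the generator is calibrated to: lesion
and WMH volume scales, the age-WMH association, rating distributions, and
neglect prevalence by the mean-CoC cutoff.
"""

import numpy as np
from scipy.stats import spearmanr

from neglectwmh import SimulationConfig, classify_neglect, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=103, seed=1))
t = cohort.table
coc = cohort.mean_coc()
neglect = np.array([classify_neglect(v) for v in coc])

print(f"patients: {cohort.n}, grid {cohort.grid} at {cohort.voxel_size_mm} mm")
print(f"age: {t.age.mean():.1f} ({t.age.std():.1f}) years")
print(f"lesion volume: {t.lesion_volume_cm3.mean():.1f} ({t.lesion_volume_cm3.std():.1f}) cm^3")
print(f"WMH volume:    {t.wmh_volume_cm3.mean():.1f} ({t.wmh_volume_cm3.std():.1f}) cm^3")
print(f"Spearman age vs WMH volume: {spearmanr(t.age, t.wmh_volume_cm3).statistic:.2f}")
print(f"CHS rating median [range]: {int(t.chs.median())} [{t.chs.min()}-{t.chs.max()}]")
print(f"Fazekas total median [range]: {int(t.fazekas_total.median())} [{t.fazekas_total.min()}-{t.fazekas_total.max()}]")
print(f"mean CoC: {coc.mean():.2f}; neglect prevalence: {neglect.mean()*100:.0f}%")
# Lesions are connected right-hemisphere blobs; WMH combine periventricular
# rims with deep punctate foci in both hemispheres and are masked by the
# lesion, so the two maps are always disjoint.
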