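"""Permutation test for moderation of the era effect by sex.

Computes the female and male two-era RMTL ratios, then re-allocates
individuals to pseudo-sex groups of the original sizes (era membership
preserved) 1,000 times; P = (1 + n_>)/(1 + n).
"""
import natexp
from natexp.scenarios import paper_like

cohort = natexp.generate_cohorts(paper_like(8000, 9600, seed=7))
landmarked = cohort[cohort["dementia_time"] > 0.25].copy()
landmarked["dementia_time"] -= 0.25

res = natexp.permutation_moderation(
    landmarked, "dementia", n_perm=1000, seed=7, tau=5.75
)
print(f"RMTL ratio, women: {res.ratio_f:.3f}")
print(f"RMTL ratio, men:   {res.ratio_m:.3f}")
print(f"observed |difference|: {res.observed_abs_diff:.3f}")
print(f"permutations exceeding observed: {res.n_exceed} of {res.n_perm}")
print(f"permutation P = {res.p_value:.4f}")
print(
    "\nA small P indicates the protective era effect differs by sex"
    "\nbeyond what label shuffling alone produces. The generative law"
    "\ngives women extra protection, but at desk-scale cohort sizes the"
    "\ntest has limited power to detect it."
)
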