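"""Compare per-embryo measurements between genotypes.

Welch's t-test and the Mann-Whitney U test on two small samples, and the
chi-square goodness-of-fit test on pooled flow-direction quadrant counts.
"""

from yolkflow.stats import compare_quadrants, mann_whitney, welch_t

wild_type = [0.42, 0.39, 0.45, 0.41, 0.44]
mutant = [0.30, 0.28, 0.35, 0.33]

w = welch_t(wild_type, mutant, tails="two")
print(f"Welch t = {w.statistic:.3f}, df = {w.df:.2f}, two-tailed p = {w.p_value:.4f}")

mw = mann_whitney(wild_type, mutant, tails="two")
print(f"Mann-Whitney U = {mw.statistic:.1f}, exact two-tailed p = {mw.p_value:.4f}")

# Pooled PIV quadrant counts (up, down, left, right) against uniformity.
chi = compare_quadrants([160, 40, 55, 45], [0.25] * 4)
print(f"chi2 = {chi.statistic:.2f}, df = {chi.df:.0f}, upper-tail p = {chi.p_value:.3g}")
# Small p-values indicate a genotype difference (t / U) or a directional
# bias of the flow field (chi-square).
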