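"""Exact binomial analysis of a two-class LOH screening outcome.

Of 19 anthocyanin-less plants, 2 were tt4-type and 17 tt8-type.  Under
equal per-gene mutability the split is very unlikely (two-sided exact
test), but weighting the null by gene length (TT4 is 1789 bp, TT8 is
4643 bp) leaves it unremarkable (one-sided exact test).
"""

from seedloh import (
    ScreeningCounts,
    binom_test_exact,
    class_ratio,
    length_weighted_null,
    mutation_frequency,
)

counts = ScreeningCounts(
    n_observed=2588, n_mutant=19, n_tt4=2, n_tt8=17, group="irradiation"
)

print(f"mutation frequency: {mutation_frequency(counts)}%")
print(f"tt8:tt4 class ratio: {class_ratio(counts)}")

equal = binom_test_exact(counts.n_tt4, counts.n_mutant, 0.5, "two")
print(f"equal-null two-sided p = {equal.p_value:.2e}  (significant, < 0.001)")

p0 = length_weighted_null(1789, 4643)
weighted = binom_test_exact(counts.n_tt4, counts.n_mutant, p0, "one-less")
print(
    f"length-weighted null p0 = {p0:.2f}, one-sided p = "
    f"{weighted.p_value:.3f}  (not significant, > 0.06)"
)
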