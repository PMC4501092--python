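"""The analytic binomial null for cross-cohort consistency counts.

If a random gene is significantly upregulated in any one cohort with
probability p = 0.32, the chance it is upregulated in at least 8 of 10
cohorts is the binomial tail ~ 0.003 — so out of a pool of 212 random
genes only ~0.5 would be expected to show that much consistency.
Observing 35 such genes is therefore overwhelming evidence of signal.
"""

from epinstab import binomial_tail, expected_random_count, meta_significance

for label, (T, m, p) in {
    "up in >=8/10 cohorts (p=0.32)": (10, 8, 0.32),
    "down in >=8/10 cohorts (p=0.34)": (10, 8, 0.34),
    "pos. corr. with HyperZ >=6/10 (p=0.12)": (10, 6, 0.12),
    "pos. corr. with HypoZ >=6/10 (p=0.16)": (10, 6, 0.16),
    "neg. corr. with HypoZ >=6/10 (p=0.25)": (10, 6, 0.25),
}.items():
    print(f"{label}: tail P = {binomial_tail(T, m, p):.2e}")

tail = binomial_tail(10, 8, 0.32)
mean, sd = expected_random_count(212, tail)
print(f"\nexpected consistently-up genes among 212 random genes: {mean:.2f} +/- {sd:.2f}")
print(f"P(observe >= 35 such genes by chance) = {meta_significance(35, 212, tail):.2e}")
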