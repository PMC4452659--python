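"""How large must |PCC| be before an edge means anything?

Computes the secure threshold -- the cutoff at which a pure-noise dataset of
the same shape yields an empty coexpression network in expectation -- for a
few (samples, genes) design points, next to the Bonferroni comparators.
"""

from coexthresh import bonferroni_threshold, secure_threshold

print(f"{'n':>5} {'m':>7} {'secure':>9} {'B_fisher':>9} {'B_t':>9}")
for n, m in [(8, 100), (10, 20), (20, 1000), (50, 1000), (100, 100_000)]:
    s = secure_threshold(n, m)
    bf = bonferroni_threshold(n, m, method="fisher")
    bt = bonferroni_threshold(n, m, method="student_t")
    print(f"{n:>5} {m:>7} {s.value:>9.5f} {bf.value:>9.5f} {bt.value:>9.5f}")

print()
res = secure_threshold(10, 20)
print(
    f"With n=10 samples and m=20 genes, an absolute correlation must exceed "
    f"{res.value:.3f} before a single edge is expected on pure noise "
    f"(expected null edges at the cutoff: {res.expected_null_edges:.3f}). "
    f"Few-sample designs demand strikingly large correlations."
)
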