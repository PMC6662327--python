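"""Central limit theorem: sums of skewed variables become normal.

The skewness of a sum of n iid variables decays as 2/sqrt(n) for the
exponential family; the classic sum of 12 uniforms has mean 6, variance 1.
"""

from popgenlab import CLTSpec, clt_sample

for n in (1, 5, 50):
    out = clt_sample(CLTSpec("exponential", n_per_sum=n, n_sums=20000,
                             mode="sum", seed=3))
    print(f"exponential(1), sum of {n:>2}: skewness {out.sample_skewness:+.3f} "
          f"(theory {2 / n**0.5:.3f})")

out = clt_sample(CLTSpec("uniform", 12, 20000, "sum", seed=4))
print(f"sum of 12 uniforms: mean {out.sample_mean:.3f} (6), "
      f"variance {out.sample_var:.3f} (1)")
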