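"""Test whether private calls have depressed depth and genotype quality.

Injects low-quality artifact calls into 0.1% of sites of a simulated passage
series, then compares each sample's depth and GQ at its private sites against
all of its other sites with a two-sided rank-sum test.  Real artifact calls
show up as significantly lower depth/quality among private genotypes.
"""

import passage_stability as ps

cfg = ps.SimConfig(genome_length=4_000_000, artifact_rate=0.001,
                   artifact_depth_shift=-10, seed=3)
cs = ps.simulate_callset(ps.simulate_truth(cfg), cfg)

print("sample   metric    n_private  n_other        U    p (two-sided)")
for sample in ("P0", "P5.1", "P10.1"):
    for metric in ("depth", "quality"):
        r = ps.compare_private_quality(cs, sample, metric)
        print(f"{sample:8s} {metric:8s} {r.n_private:9d} {r.n_other:8d} "
              f"{r.statistic:9.0f}    {r.p_two_sided:.3g}")
print()
print("Small p-values mean the sample's private genotypes have systematically")
print("lower depth/GQ than its shared ones — the signature of calling")
print("artifacts rather than true culture-acquired mutations.")
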