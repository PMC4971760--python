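"""Posterior-mean quantification with an informative vs a uniform prior.

A single gene with two isoforms sharing most of their reads: the with-peak
pseudocount (0.60) pulls ambiguous reads toward the isoform with TSS
evidence, while the uniform pseudocount-1 baseline splits them evenly.
"""

from peakprior import CompatibilityMatrix, PriorSpec, gibbs_quantify

# 30 reads compatible with both isoforms, 6 unique to B1, 2 unique to B2
compat = CompatibilityMatrix(
    read_ids=[f"r{i}" for i in range(38)],
    alignments=[[("B1", 0), ("B2", 0)]] * 30
    + [[("B1", 1)]] * 6
    + [[("B2", 1)]] * 2,
)
ell = {"B1": 800.0, "B2": 800.0}

informative = PriorSpec(
    partition_model="two_partition_peak",
    alphas={1: 0.60, 2: 0.04},
    assignment={"B1": 1, "B2": 2},
)
uniform = PriorSpec.uniform(["B1", "B2"], pseudocount=1.0)

for name, prior in (("informative", informative), ("uniform-1", uniform)):
    post = gibbs_quantify(compat, ell, prior, n_samples=500, burn_in=200, seed=3)
    c1 = post.at["B1", "posterior_mean_count"]
    c2 = post.at["B2", "posterior_mean_count"]
    print(f"{name:12s} counts: B1 (with peak) = {c1:6.2f}   B2 (no peak) = {c2:6.2f}")
# The informative prior moves shared reads from the no-peak isoform to the
# with-peak isoform; unique reads keep both estimates anchored to the data.
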