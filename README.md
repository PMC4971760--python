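# peakprior

ChIP-seq-informed Dirichlet priors for RNA-seq isoform quantification.

## The problem

Short RNA-seq reads are frequently compatible with several alternatively
spliced isoforms of a gene (or with several genes), and some isoforms are
*indistinguishable*: every fragment they can generate also aligns to another
isoform, so no amount of sequencing depth can apportion their abundance from
reads alone.  Transcription evidence at the transcription start site (TSS) —
RNA polymerase II or histone-modification ChIP-seq peaks — is informative
about which isoforms are actually transcribed.  `peakprior` turns that
evidence into a prior over transcript abundances and uses it to steer the
allocation of multimapping reads.

It is aimed at computational biologists who quantify bulk RNA-seq at the
isoform level and have matched (or even unmatched) ChIP-seq peak calls
available, and at methodologists who want a compact, fully testable
implementation of prior-guided quantification with a built-in simulation
harness.

## The model

Reads are modelled generatively: a fragment originates from isoform *i*
with probability θᵢ and from a start position uniform over the isoform's
effective length ℓ̃ᵢ (the number of valid fragment starts).  Maximum
likelihood estimation by EM maximises

L(θ) = ∏ᵣ Σ_{(i,p)∈Aᵣ} θᵢ/ℓ̃ᵢ,

where Aᵣ is read *r*'s alignment set.  For the Bayesian estimator, θ is
given a Dirichlet prior whose parameters are *learned from the data*:

1. Isoforms are partitioned by external evidence — by default, whether a
   ChIP-seq peak overlaps the 500-nt flanking region of the isoform's TSS.
   Isoforms of one gene with TSSs within 500 nt are clustered into *isoform
   TSS groups* that share peak status.
2. On a training set of isoforms whose ChIP evidence is uniquely assignable
   (TSS windows and gene spans overlapping nothing else), one pseudocount
   α_g per partition is learned by maximising the Dirichlet-multinomial
   likelihood of the isoforms' ML fragment counts n:

   ln P(n | α) = ln Γ(N+1) − Σ ln Γ(nᵢ+1) + ln Γ(A) − ln Γ(N+A)
                 + Σ [ln Γ(nᵢ+α_{g(i)}) − ln Γ(α_{g(i)})],  A = Σᵢ α_{g(i)}.

3. All isoforms are partitioned the same way and quantified by a collapsed
   Gibbs sampler in which each α acts as a prior fragment count:
   P(z_r=(i,p) | z₋ᵣ) ∝ (αᵢ + nᵢ^{−r})/ℓ̃ᵢ over Aᵣ.  Posterior-mean counts
   and TPM are reported alongside the ML estimates.

Candidate prior sources (different marks, cell lines, partition models) are
ranked by training-set log-likelihood, and a permutation test decides
whether a partitioning is informative at all.  A simulation module draws θ
from the partitioned Dirichlet, emits structurally multimapping fragments,
and scores estimators by false-positive rate (FPR, % of truly unexpressed
units called expressed) and false-negative rate (FNR) at a TPM cutoff.

## Worked example

`examples/learn_prior.py` builds a synthetic genome whose expression
correlates with peak placement, quantifies its reads, and learns the prior:

```
training isoforms: 56
partition 1 (with peak): alpha = 0.6806  (29 isoforms)
partition 2 (no peak): alpha = 0.0460  (27 isoforms)
training log-likelihood: -281.275
```

The with-peak pseudocount is ~15× the no-peak one: with-peak isoforms carry
real fragment mass while most no-peak isoforms have none.
`examples/quantify_with_prior.py` then shows what the prior does to a gene
whose two isoforms share 30 of 38 reads:

```
informative  counts: B1 (with peak) =  28.70   B2 (no peak) =   9.30
uniform-1    counts: B1 (with peak) =  26.45   B2 (no peak) =  11.55
```

Shared reads move toward the isoform with TSS evidence.  On the
shared-structure benchmark (`examples/simulate_and_benchmark.py`, 10
replicates) the informative prior cuts the isoform-level FPR from 100% to
~70% against the uniform pseudocount-1 baseline at the cost of a ~0.3-point
FNR increase — silent no-peak isoforms now receive only 0.04 pseudo-
fragments, so shared reads and prior mass no longer push them over the
expressed threshold.

There is also a thin CLI mirroring the three-step workflow:

```sh
peakprior make-fixtures --out fx --seed 0
peakprior prepare      --annotation fx/fixture.gtf --out prep
peakprior train-prior  --annotation fx/fixture.gtf --peaks fx/peaks.narrowPeak \
                       --alignments fx/reads.sam --out prior
peakprior quantify     --annotation fx/fixture.gtf --alignments fx/reads.sam \
                       --prior prior/learned --out quant.tsv --seed 7
```

## Layout

- `src/peakprior/annotation.py` — GTF parsing, TSS groups, effective
  lengths, structural distinguishability
- `src/peakprior/chip.py` — peaks, TSS windows, training set, DM prior
  learning, source comparison, informativeness test
- `src/peakprior/quantify.py` — compatibility matrix, EM, collapsed Gibbs,
  gene aggregation, expressed calls
- `src/peakprior/simulate.py` — θ draws, fragment simulation, subsampling,
  FPR/FNR scoring, benchmark harness
- `src/peakprior/benchmark.py` — canonical benchmark study conditions
- `src/peakprior/fixtures.py` — deterministic synthetic genome
- `src/peakprior/cli.py` — the command-line front end
- `docs/methods.md` — modelling assumptions, defaults and limitations
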