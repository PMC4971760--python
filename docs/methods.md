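# Methods

## Read model and estimators

A sequenced fragment is assumed to originate from isoform *i* with
probability θᵢ and from a start position uniform over the isoform's
effective length ℓ̃ᵢ.  The evidence per read is its *compatibility set*:
the (transcript, position) pairs it can align to.  This is a deliberate
simplification of full RNA-seq read models — there are no quality scores,
no sequencing-error model, no positional or GC bias, and no noise
transcript inside the inference model.  The package's contribution is the
prior, not the read model, and every property we test is a property of the
prior-guided allocation, which this reduced model isolates cleanly.

**EM (maximum likelihood).**  Reads with identical compatibility transcript
multisets are collapsed into equivalence classes; EM iterates
responsibilities γ ∝ θᵢ/ℓ̃ᵢ and updates θᵢ = Σγ/N until the relative
log-likelihood change falls below 1e-8 (at most 1e4 iterations, θ
initialised uniform).  The log-likelihood is asserted non-decreasing at
every step.  TPMᵢ = 1e6·(θᵢ/ℓ̃ᵢ)/Σⱼ(θⱼ/ℓ̃ⱼ); ML expected counts sum to N
exactly.

**Collapsed Gibbs (posterior mean).**  Under a Dirichlet(α) prior on θ the
read assignments are resampled with P(z_r=(i,p) | z₋ᵣ) ∝ (αᵢ+nᵢ^{−r})/ℓ̃ᵢ.
Defaults: 1000 samples after 500 burn-in, a single chain, assignments
initialised by sampling once from the EM responsibilities.  The
posterior-mean count is the post-burn-in average of nᵢ and the
posterior-mean θᵢ the average of (αᵢ+nᵢ)/(A+N); since the latter is linear
in nᵢ it is computed from the averaged counts.  Posterior-mean TPM is
computed from posterior-mean θ (not the mean of per-sample TPMs); this
keeps the TPM identity Σ TPM = 1e6 exact and makes the all-unique-read case
agree with the conjugate closed form to machine precision.  Runs are
bit-reproducible given a seed; the inner loop is a numba kernel seeded from
the same integer.

## Annotation conventions

Genomic intervals are 0-based half-open internally; GTF input is converted
on read (chosen for BED/narrowPeak interoperability).  The TSS is the
biological 5′ end: first exon start on `+`, last exon end − 1 on `-`.
Isoform TSS groups are single-linkage clusters of one gene's TSSs at an
inclusive 500-nt threshold; the group representative is the minimum member
TSS.  Effective length is the number of valid fragment starts:
max(ℓ−L+1, 1) for a fixed fragment length, expectation over the length
distribution otherwise.

**Distinguishability** is structural, not sequence-based: a fragment of
isoform *i* (its genomic exonic footprint) is compatible with isoform *j*
iff the footprint is reproduced exactly as a contiguous stretch of *j*'s
exon chain.  An isoform is indistinguishable when it has no witness
fragment compatible with nothing else.  Cross-locus multimapping is
modelled by explicit homology groups (transcripts declared mutually
alignable at the same transcript coordinate) because no sequences are
handled; this keeps the simulator deterministic and aligner-free, at the
cost of idealising homologs as structurally identical.

## Prior learning

**TSS windows.**  A unit's window is [TSS−flank, TSS+flank] inclusive
(default flank 500 nt; 100 nt for 5′-end signal extraction).  A TSS group
uses the union of its members' windows, consistent with counting a 5′ read
once per group.  Window signal is the sum of overlapping peak signals
(narrowPeak `signalValue`, BED6 `score`), each peak counted once.

**Training set.**  Isoforms qualify when their TSS group's window overlaps
no other group's window and their gene's exonic span overlaps no other
gene — conservative, configurable stand-ins for "ChIP reads and peaks can
be uniquely assigned".  Fragment counts are the ML expected counts,
accepted as fractional values directly through log-Γ (no rounding).

**Dirichlet-multinomial fit.**  One α per partition maximises the DM
log-likelihood, optimised on ln α with L-BFGS-B inside [1e-4, 1e4] from
α = 1 (convergence 1e-6 on the log-likelihood), with a Nelder–Mead retry
and a coordinate-wise bounded polish because quasi-Newton steps stall on
the flat plateaus that arise when a partition's MLE sits at a bound
(e.g. strongly underdispersed counts drive α to the upper bound along an
asymptotically flat likelihood).  The α-constant multinomial coefficient is
retained so reported log-likelihoods are true log-probabilities for integer
counts.

**Partition models.**  Peak/no-peak (default), single partition, signal
quantiles (k groups), peak-plus-signal (no-peak, then a median-signal split
of the with-peak side), and a logistic-regression combination of several
signal tracks (features log1p(signal) per mark, response "ML TPM ≥ 1",
threshold 0.5).  The quantile, peak-plus-signal and logistic constructions,
and the informativeness test below, are this package's own constructions of
ideas whose published descriptions are incomplete; they are labelled as
such rather than claimed as re-implementations.

**Source comparison and informativeness.**  Candidate partitionings of the
same training counts are ranked by maximised log-likelihood (ties broken by
name).  The informativeness test compares the two-partition maximised
log-likelihood against the single-partition one (non-negative by nesting)
and permutes labels for the null; p = (1+#{perm ≥ obs})/(B+1).  The test is
exact-by-permutation and mildly conservative when the statistic ties at
zero, which happens for very sparse, strongly overdispersed counts.

## Simulation harness

θ is drawn from the partitioned Dirichlet; transcripts may be pinned to
θ = 0 to represent truly unexpressed units.  Each fragment is noise with
probability 0.05 by default (counted in depth, never aligned — the noise
level is a package default, configurable), otherwise its origin follows θ
and its start is uniform; its alignment set is every structurally
compatible transcript plus declared homologs.  Subsampling draws
⌊f·N⌋ reads without replacement.  FPR is the percentage of truly
unexpressed units called expressed, FNR the percentage of truly expressed
units called unexpressed, at an inclusive TPM cutoff (a unit with TPM
exactly at the cutoff is expressed); empty denominators give 0.

**Shared-structure benchmark conditions.**  80 genes, each with two
structurally identical 1-kb isoforms; the with-peak isoform's θ comes from
the Dirichlet component with pseudocount 0.60, the no-peak twin is pinned
to zero; 50 000 fragments of length 100, 5% noise; Gibbs runs shortened to
150 samples / 100 burn-in (posterior means at this data size are stable
well below the decision threshold's granularity).  The expressed boundary
is set at 0.76 fragment-equivalents of abundance.  Rationale: the
interesting regime is where prior pseudocounts are commensurate with the
decision boundary — at genome scale the conventional 1 TPM corresponds to
a sub-fragment count, sitting between the learned no-peak pseudocount
(0.04) and the uninformative baseline (1).  A desk-scale transcriptome has
far fewer transcripts, so the boundary must be restated in fragment
equivalents to probe the same mechanism; 0.76 places it strictly between
the two pseudocounts.  Under these conditions the uniform-1 baseline calls
every silent isoform expressed, the informative prior rescues the silent
isoforms of all but the most highly expressed genes, and the FNR ordering
reverses, as expected when the informative with-peak pseudocount (0.60) is
slightly below the boundary while the uniform pseudocount (1) is above it.

**What the generator does not emulate.**  Sequence content, mappability,
sequencing errors, fragment-length variability within a run, positional
bias, and library-preparation artefacts.  Passing tests therefore
demonstrate correctness of the allocation machinery and the direction and
rough magnitude of the prior's effect, not end-to-end accuracy on real
libraries.

## Numerical and degenerate-input choices

- α bounds 1e-4..1e4; optimisation on ln α; init α = 1.
- Fractional counts throughout via log-Γ.
- Equal-probability Gibbs ties are resolved by the sampled uniform
  variate; seeds below 2³¹ feed both the numpy generator and the kernel.
- Zero-read quantification, unknown transcripts, inverted peak intervals,
  non-positive cutoffs/pseudocounts/fragment lengths, constant labels and
  empty training sets raise immediately with actionable messages.
- `signal_quantile` refuses degenerate signal distributions rather than
  silently merging groups.

## Known limitations

- Positions within a transcript are uniform; fragment-length distributions
  enter only through effective lengths.
- The training-set uniqueness rules are conservative; on tiny annotations
  they can exclude most isoforms (the error message says so).
- The logistic partition model fits on the training units only and is not
  regularisation-tuned; it is a baseline combiner, not a classifier study.
- Single-chain Gibbs without convergence diagnostics; the conjugate
  structure makes mixing benign for the problem sizes targeted here, but
  very large compatibility classes would deserve multiple chains.
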