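# Methods

This note documents the models, numerical choices and limitations behind
`kmertopics`: what each stage computes, which knobs matter, and what the
synthetic fixtures do and do not demonstrate.

## Genomes as documents

A genome is normalized to an uppercase IUPAC string. Multi-record inputs
(chromosome + plasmids, draft contigs) are joined with a single `-`
separator; because the separator is outside the k-mer alphabet, no window
can span a record boundary, which keeps the decomposition correct for
incomplete assemblies. `length_bp` counts nucleotides only. Ambiguity codes
(N, R, Y, …) are kept in the sequence and excluded at extraction time — one
single point of filtering.

K-mer windows slide with step 1; any window containing a character outside
{A, C, G, T} is skipped, so a clean single-record genome of length *l*
yields exactly *l − k + 1* windows. Counting is forward-strand only: the
method treats a genome as a text, and no reverse-complement
canonicalization is applied (the choice is isolated in one code path should
a canonical variant ever be wanted). Words are packed two bits per base
into 64-bit integers, which bounds k at 31; the sorted integer order equals
lexicographic order over {A < C < G < T}, so vocabularies are canonical.

## Word-length selection by cumulative relative entropy

For word length *j*, the genome's observed j-mer distribution is compared
with a second-order Markov extrapolation built from its own (j−1)- and
(j−2)-mer frequencies:

    expected(n1…nj) = f(n1…n_{j−1}) · f(n2…nj) / f(n2…n_{j−1})

RE_j is the Kullback–Leibler divergence (base 2, so bits) of observed from
expected, and CRE(k) = Σ_{j≥k} RE_j. The working k is the smallest one with
CRE(k) below a threshold (default 0.1 bits) for *every* genome — the point
where longer words stop adding information over what shorter words already
predict, while the 4^k cost keeps growing.

Numerical choices:

* every sub-word of an observed word is itself observed, so the expectation
  is positive on the whole observed support; the expectation generally does
  not sum to 1 and is renormalized over that support, which by Gibbs'
  inequality makes RE_j ≥ 0 (tiny negative rounding residues are clamped
  to 0);
* the tail sum is truncated at `k_max` (default 16, the exact in-memory
  counting horizon); CRE(k_max) = RE_{k_max} by construction;
* the plug-in KL estimate carries a positive sampling bias of order
  4^j·(3/4)/(2·N·ln 2) for N windows. At N = 10^6 this is ≈ 0.03 bits by
  j = 8, which is why the entropy tests probe j ≤ 7 at megabase scale:
  beyond that the bias, not the Markov structure, dominates. Real bacterial
  genomes (N ≈ 10^6–5·10^6) sit near this regime at j = 13 as well, so
  absolute CRE values at large j should be read as upper bounds.

## Corpus

The document-term matrix holds occurrence **counts** (LDA consumes word
multiplicities). The document-frequency filter keeps words present in at
least `min_df` genomes (default 10, the per-family genome count in the
reference corpus; also expressible as a fraction of documents for other
collection sizes). The corpus summary reports, besides the retained
vocabulary size, the *presence sum* Σ_v df(v) — the number of
(genome, word) presence pairs over the retained vocabulary — which is the
statistic comparable across studies that report "words found overall".
Storage is sparse CSR throughout (V can exceed 10^5 at k = 13), serialized
as MatrixMarket plus plain-text vocabulary/doc-id sidecars.

## Topic model

Collapsed Gibbs sampling with the conventional Gibbs-LDA defaults
α = 50/T, β = 0.1, 2000 sweeps (half discarded as burn-in when sample
averaging is requested). All are overridable. Design points:

* **Determinism.** One seeded NumPy generator drives initialization and all
  uniforms; the inner loop (Numba-compiled, with an op-for-op identical
  pure-Python mirror used in tests) is single-threaded. Identical
  (corpus, config, seed) reproduce the chain bit for bit, including across
  the chunked pre-drawing of uniforms.
* **Point estimate.** θ and φ are the smoothed posterior means of the final
  state, θ_dj = (n_dj + α)/(n_d + Tα), φ_jv = (n_jv + β)/(n_j + Vβ) —
  the common package behavior. An option averages post-burn-in samples
  after aligning topics (Hungarian assignment on φ rows, L1 cost); topic
  labels are only identified up to permutation, so every cross-fit
  comparison in the tests aligns topics first.
* **Token stream.** Counts are expanded to tokens in vocabulary order
  within each document. The model is exchangeable, so the layout affects
  only the chain's path, not the posterior.
* **Document lengths.** The generative story draws N ~ Poisson(ξ), but
  lengths are observed at inference time; ξ exists only in the synthetic
  generator.

Correctness is checked two ways: the full-conditional formula is compared
against ratios of the exactly enumerated collapsed posterior on tiny
corpora, and the chain's empirical state distribution over 10^5 sweeps is
compared to that enumerated posterior by a chi-square goodness-of-fit test.

## Clustering and scoring

Distances between θ rows default to Euclidean (Jensen–Shannon divergence in
bits is available); linkage defaults to average (UPGMA). Both choices are
recorded in the run report because a dendrogram is only reproducible given
them. Trees are exported as Newick with branch lengths taken from merge
heights (leaves at height 0, hence ultrametric for average linkage); flat
cuts remove the top merges and always yield the requested number of
clusters. Agreement with families is scored by purity (fraction of genomes
whose cluster's majority family is their own, majority ties broken toward
the lexicographically smallest family) and by the adjusted Rand index under
the permutation model, implemented from the contingency table and verified
against scikit-learn.

## Frequency-profile baseline

The same genomes are also compared classically: normalized k-mer frequency
vectors over the *same filtered vocabulary* as the topic model (an
unfiltered-union option exists), pairwise Jensen–Shannon divergence
(base 2, bounded by [0, 1]), and the same clustering machinery. No over- or
under-represented words are removed, so the comparison isolates what the
topic layer adds over raw composition.

## Synthetic data: what it emulates, what it does not

* `generate_corpus` draws bag-of-words corpora exactly from the generative
  process (Poisson length, per-token topic then word). Defaults are the
  study-scale conditions used throughout the tests: T = 3 topics over
  V = 1000 words (topic rows from a sparse Dirichlet(0.1)), M = 30
  documents in 3 families of 10, mean length ξ = 5000, each family placing
  0.8 of its mass on its own topic — clearly separated families that are
  nevertheless genuine mixtures.
* `generate_markov_genome` samples order-m chains over {A, C, G, T}; for
  j ≥ m + 2 the second-order extrapolation is exact in expectation, which
  is the calibration target of the entropy tests.
* `generate_family_genomes` builds DNA by concatenating words sampled from
  a family's topic mixture (default: 300 distinct 8-mers, 30 genomes of
  12 kb). Concatenation creates junction windows the planted model does not
  describe — at least 1/k of windows are planted tokens, the rest junction
  noise. No attempt is made at de Bruijn-consistent design: the noise floor
  is quantifiable and the pipeline has to tolerate unmodeled windows on
  real genomes anyway. Junction words recur within families and so carry
  family signal themselves; passing these tests therefore shows the
  pipeline recovers strong compositional family structure from sequence,
  not that it would resolve subtler real-world divergences (no evolutionary
  model — substitutions, indels, rearrangements, phylogenetic signal — is
  simulated).

## Pipeline

`run_pipeline` executes reading → (optional) entropy-based k selection →
corpus → LDA → clustering (+ baseline), writing corpus statistics, CRE
profiles, θ/φ tables, Newick trees, cluster assignments with agreement
scores, and an echo of the fully resolved configuration. Outputs are
byte-reproducible for identical inputs, config and seed; timestamps appear
only in logs. Stage failures are re-raised tagged with the stage name. The
topic count T is a required user input (3 in the reference analysis,
matching the three families): the package deliberately performs no
automatic topic-number search.

## Problem sizes used in the checks

The automated checks run at desk scale: sampler exactness on ≤ 6-token
corpora (exact enumeration is O(T^n)); recovery at the default study
conditions above (≈ 150k tokens, 2000 sweeps, 10 seeds); entropy behavior
on megabase Markov sequences (5 replicates per order, j ≤ 7); DNA-level
family recovery on 30 × 12 kb genomes. The reference 30-genome reproduction
(91 Mb of sequence, k = 13) runs only when the user has fetched the
accessions listed in `data/table1/manifest.tsv`, since the package never
downloads data itself.

## Known limitations

* Forward-strand counting means strand-flipped assemblies of the same
  genome produce different word bags.
* Exact counting bounds k at 31 (packing) and practically at ~16 (memory);
  there is no sketching/minimizer path.
* The CRE threshold (0.1) is in bits and unit-dependent; changing the
  logarithm base changes its meaning.
* Gibbs LDA point estimates inherit Monte Carlo variability; different
  seeds can yield slightly different θ (the tests quantify this at the
  default conditions).
* No plasmid/chromosome weighting: all records of an accession contribute
  tokens in proportion to their length.
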