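# Methods

## The generative model

`pathmet` treats an untargeted metabolomics experiment as the observable end
of a three-layer generative process over a metabolic model with `I` pathways,
`J` metabolites and `K` discretized mass bins:

1. **Pathway activity.** Each pathway is independently active with
   probability λ: `a_i ~ Bernoulli(λ)`. λ can be fixed or given a conjugate
   Beta(α, β) hyperprior (the default, with α = β = 1) and sampled.
2. **Metabolite production.** An active pathway produces each of its member
   metabolites independently with probability μ (`z_ij ~ Bernoulli(μ)` when
   `a_i = 1` and metabolite j is on pathway i; 0 otherwise). A metabolite is
   present if any pathway produced it: `m_j = [Σ_i z_ij > 0]`.
3. **Detection.** Each present metabolite is detected with probability γ
   ("observed accuracy" of the instrument). Bin k is observed (`w_k = 1`)
   when at least one of its candidate metabolites `J_k` is detected.

Because a metabolite has exactly one mass, the candidate sets `J_k`
partition the metabolites and the likelihood factorizes over bins. The
production matrix Z is never sampled: with `n_j(a)` the number of active
pathways containing metabolite j,

    φ_j(a) = 1 − (1 − μ)^{n_j(a)}          (probability j is present)
    p(w_k = 0 | a) = Π_{j∈J_k} (1 − γ φ_j(a)),   p(w_k = 1 | a) = 1 − p(w_k = 0 | a)

so only the binary vector `a` carries the inference.

## Inference

A collapsed Gibbs sampler draws from `p(a | w) ∝ p(a) p(w | a)`. Each sweep
updates every `a_i` from its full conditional in a systematic scan, then (in
Beta mode) draws `λ | a ~ Beta(α + Σa, β + I − Σa)`. Flipping `a_i` only
changes the survival factors of metabolites on pathway i, so the conditional
log-odds are accumulated over the bins whose candidate sets touch pathway i;
the affected bins' terms are recomputed from the exact integer counts `n_j`
on every update, so there is no floating-point drift, and the result is
identical to a full likelihood recomputation (a property the test suite pins
exactly). All likelihood math is in log space; products over large candidate
sets are sums of logs, with `log(1 − e^x)` evaluated through `expm1`/`log1p`
on the appropriate branch.

Choices worth stating:

- **Initialization** is the all-active state, the unique state guaranteed a
  positive likelihood whenever the observations are attainable (any
  all-inactive start has probability zero as soon as one bin is observed).
- **Burn-in semantics**: `n_samples` (default 1000) is the total number of
  sweeps and the first `n_burn_in` (default 100) are discarded, so 900 are
  retained by default. No thinning is applied.
- **Uncertainty**: the Monte-Carlo standard error of each posterior mean is
  estimated by batch means with 20 batches. For near-constant chains this
  estimator degenerates to zero; consumers that use it as an agreement
  tolerance should floor it (the test suite floors at 2×10⁻³).
- **Attainability**: if an observed bin has no candidate on any pathway, the
  model assigns the data probability zero under every state. This is raised
  as an error naming the bin before sampling starts, with a hint to check
  the binning tolerance and model completeness.
- A single chain is the default; `n_chains` runs independent seeded chains
  and pools the retained draws.

For models with at most 20 pathways, `exact_posterior` enumerates all `2^I`
states with a numerically stable log-sum normalization. It exists as a
verification oracle — the test suite requires the sampler's means to agree
with enumeration within Monte-Carlo error — and is also useful directly on
small models.

## Annotation posteriors

Presence posteriors `p(m_j = 1 | w)` reuse the retained pathway draws; no
additional sampling is run. Conditioned on `a`, metabolite j interacts only
with its own bin's observation, through the joint table

    p(m_j=0, w_k=0 | a) = (1 − φ_j) · P
    p(m_j=0, w_k=1 | a) = (1 − φ_j) · (1 − P)
    p(m_j=1, w_k=0 | a) = φ_j (1 − γ) · P
    p(m_j=1, w_k=1 | a) = φ_j (1 − (1 − γ) · P),   P = Π_{j′∈J_k, j′≠j} (1 − γ φ_j′)

normalized at the observed `w_k`. The per-draw computation is vectorized
over all J metabolites through a sparse metabolite-to-bin indicator;
correctness is defined by equality with the scalar per-metabolite formula
and, on tiny models, with brute-force enumeration of the full production
matrix. Candidates of each observed bin are ranked by posterior (ties broken
lexicographically by id); the reported annotation set is every candidate
within 10⁻⁹ of the maximum — true ties are exact because all candidates are
averaged over the same draws, so the tolerance only absorbs float noise.
Metabolites in unobserved bins are still scored (with γ < 1 their posterior
quantifies presence-without-detection); metabolites on no pathway have
φ = 0 and posterior 0.

## Fixed annotations (τ restriction)

External annotations (e.g. spectral-library matches) can fix a bin to a
single metabolite before inference. The bin's candidate set shrinks to the
named metabolite and the displaced candidates become bin-less: they can no
longer explain, or be explained by, any observation, but they remain in the
model and are still scored by their prior presence probability φ.

## Mass binning and ionization

Bins are built from the model's metabolite masses only (measurements never
move bin centers): distinct masses are sorted and agglomerated in one greedy
pass, starting a new bin when the next mass is more than `ppm_tol` (default
15 ppm, relative to the running mean) away; the center is the mean of the
member masses and every metabolite is then assigned to its nearest center.
Measured m/z values are converted to neutral masses by subtracting (positive
mode) or adding (negative mode) one proton mass (1.007276466 Da,
configurable); adducts other than ±1 proton, isotopes, fragments and higher
charge states are assumed corrected upstream. A measurement is matched to
its nearest center only, and kept only within `ppm_tol` of that center
(relative to the center); a mass inside the tolerance of two centers goes to
the nearest with a logged warning, and unmatched masses are reported rather
than dropped. Pathological mass chains could in principle drift a member
slightly beyond the tolerance of its final bin mean; `validate()` enforces
the tolerance invariant at construction, and realistic mass lists (and the
packaged generators) never trigger it.

## Enrichment baseline

The comparison baseline scores each pathway by its enrichment ratio — the
fraction of its metabolites whose bin is observed, where a shared bin marks
all its candidates as putatively measured. Significance uses a one-sided
(greater) Fisher's Exact Test on the 2×2 table of measured/unmeasured
metabolites inside versus outside the pathway, over all model metabolites;
p ≤ 0.05 flags enrichment, with no multiple-testing correction. The
alternative null (against measured masses only) was considered and not
adopted because the metabolite-level table matches the ratio's numerator and
denominator semantics.

## Synthetic ground truth

Because no real untargeted dataset is fully annotated with known pathway
activities, validation is synthetic: a fraction of pathways is activated
uniformly at random, each active pathway generates a fraction of its
members (round-half-up, at least one when the fraction is positive — small
pathways would otherwise contribute nothing at 0.05), shared metabolites may
be selected independently by each active pathway, and detection is
Bernoulli(γ) mapped through the bins. The default benchmark grid crosses
pathway fractions {0.3, 0.5, 0.7} with metabolite fractions {0.05, 0.10,
0.15, 0.20, 0.25, 0.50, 0.75} at γ = 1 — noise-free detection isolates the
inference question from instrument noise. The desk-scale default runs 10
replicates per cell on a bundled random topology of 50 pathways and 800
metabolites whose summary statistics mirror genome-scale models assembled
from pathway databases: lognormal pathway sizes (a few large maps, many
small pathways), Zipf-weighted membership creating hub metabolites shared
by dozens of pathways (currency compounds, central intermediates), every
metabolite on at least one pathway, and half the metabolites isobaric with
another — giving roughly two metabolites per unique mass, as in organism
models where unique masses number about half the metabolites — with
heavy-tailed isobar families rather than mere pairs (sugar and amino-acid
isomer groups). These features matter: on a *uniform* random topology with
few collisions and no hubs, the enrichment ratio faces almost no
measurement-to-metabolite ambiguity and becomes an unrealistically strong
baseline; the ambiguity the generative model exists to resolve lives in the
hub sharing and the isobar families. `--full-paper-grid` raises the
replicates to 100 for users with more time or their own model files.

What the simulation does **not** emulate: intensities, retention times,
adduct ladders, isotope envelopes, instrument bias toward compound classes,
or correlated pathway activity. Passing benchmarks therefore demonstrate
that the inference machinery recovers the generative process it assumes —
not that the model is a complete description of a real instrument.

## Evaluation conventions

AUC follows the Mann–Whitney convention (ties count half), undefined when
ground truth has a single class (reported as NaN, never imputed). Activity
calls use an inclusive threshold (posterior ≥ 0.5 by default). Precision
with no positive calls is NaN and excluded from averages, with the exclusion
counted. Benchmark AUCs are computed per replicate and then averaged.
Annotation comparisons against an external reference are classified as
agreement (sets equal), semi-agreement (reference a proper subset of the
reported set), disagreement (no containment — including partial overlap,
which is noted), only-model (empty reference); against an isomer-level
reference, clarification (the reference isomer class contains a reported
candidate) and model-incompleteness (reference compound absent from the
model).

## Problem sizes in the shipped checks

The packaged checks run at sizes chosen to keep a full validation cycle on
one CPU comfortable: sampler-vs-enumeration agreement uses models with up to
8 pathways and 30 metabolites at 4000 sweeps, and the directional benchmark
uses the 50×800 topology above with 10 replicates per cell. The published
case-study numbers from genome-scale models (86 pathways / 1534 metabolites
and larger) require those external model and measurement files; with
model TSVs supplied, `pathmet run` and `pathmet validate` operate at that
scale unchanged.

## Known limitations

- Pathway activities are a priori independent; substrate–product coupling
  between pathways is not modeled.
- A scalar μ is shared by all pathway–metabolite pairs (the API leaves room
  for a per-pair matrix, which the sampler does not yet accept).
- Exact enumeration is limited to 20 pathways by design.
- The sampler is exact but serial; very large models pay O(T · Σ_i |bins
  touching pathway i|).
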