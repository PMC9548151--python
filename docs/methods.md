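# Methods

## Model

Both classifiers are small bidirectional gated-recurrent-unit (GRU)
networks over a fixed loci × features matrix.  Per timestep, with sigmoid
gates and tanh candidate,

    z_t = σ(x_t W_z + h_{t−1} U_z + b_z)
    r_t = σ(x_t W_r + h_{t−1} U_r + b_r)
    ĥ_t = tanh(x_t W_h + (r_t ⊙ h_{t−1}) U_h + b_h)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ ĥ_t

One GRU runs 5′→3′ and one 3′→5′; their per-locus states are concatenated.
The **SNV model** (input 11 × F) crops everything except the concatenated
state at the target locus (index 5) — the recurrent pass distils the
context into that single state, which keeps the dense head small.  The
**indel model** (input 58 × F) keeps only each direction's final state
(forward at the last locus, backward at the first).  Either head feeds a
ReLU dense stack with inverted dropout and a single sigmoid output.
Training minimises mean binary cross-entropy with Adam; the parameter
snapshot with the smallest validation log loss is returned (early stopping
patience 10, at most 200 epochs by default; the pipeline runs use 60).
The whole network is implemented in numpy in `flankrnn.nn` with analytic
backpropagation through time; the test suite checks every parameter block
against central-difference numerical gradients.

Padding is handled by an explicit indicator: windows are built in
standardized feature space where padding rows are zero (the training-set
feature mean), and a 0/1 padding channel is appended, so the nets consume
F + 1 input channels and can learn to discount padded loci.  An
alternative — masked recurrence — would complicate BPTT for no measurable
benefit at these window lengths.

Score semantics: outputs in (0,1) are pathogenicity probabilities with a
natural 0.5 cutoff shared by the SNV and indel models, which is what makes
the two score sets poolable (checked by the pooled-AUC compatibility
analysis).

## Feature schema and preprocessing

The schema is an ordered list of 28 features — 16 functional scores, 8
conservation scores, 4 allele-frequency features — with a per-feature
orientation flag.  Some raw tools score benign-high; harmonization flips
those columns on load so that larger always means more damaging, a rule the
schema records explicitly because annotation sources are heterogeneous.
Concrete names default to the widely used tool set (SIFT, PolyPhen-2
HDIV/HVAR, MutationAssessor, PROVEAN, VEST4, M-CAP, REVEL, MutPred, MVP,
PrimateAI, DEOGEN2, CADD, fathmm-XF, Eigen, GenoCanyon; GERP, phyloP ×3,
phastCons ×3, SiPhy; AF from 1000GP/ExAC/gnomAD-exomes/gnomAD-genomes), but
the schema is configuration-driven so synthetic features substitute freely.

AF features are max-subpopulation allele frequencies; a variant absent from
a dataset gets AF = 0, never "missing" — absence is information.  The
remaining 24 scores may be missing and are imputed by iterative low-rank
completion: fill with column means, then alternate a rank-r truncated SVD
reconstruction of the column-centred matrix with re-imposition of observed
entries.  The rank (capped at 10) is chosen automatically by holding out
~10% of *observed* entries and picking the rank that reconstructs them
best; on large tables the rank is selected on a 4000-row subsample.  This
held-out selection matters: with rank chosen too generously, the initial
fill is a fixed point of the iteration and an exactly low-rank matrix is
never completed correctly.  Convergence tolerance 1e-8 on the maximum
relative change of imputed entries, at most 500 sweeps, with a warning plus
column-mean fallback on non-convergence.  The procedure is deterministic
given its seed (which only picks the held-out entries).

After imputation all 28 features are standardized with per-column mean and
*population* (÷ n) standard deviation — the convention is arbitrary but
fixed — estimated on training-split target rows only and reused verbatim
for validation, test and prediction.  Raw scores are used (not rank
scores), and AF columns are standardized together with the rest;
AF-masking replaces them with the standardized value of AF = 0 so a masked
prediction needs no retraining.  Zero-variance columns and fully missing
columns are hard errors.

## Windows

`locate_codon` maps a genomic position to (codon index, within-codon
offset) by enumerating CDS positions in coding orientation, so it is
strand-aware and handles codons split across exons.  The SNV retrieval
window is the affected codon ± 1 codon (≤ 9 coding bases, ≤ 5 per side);
context loci average the feature vectors of their missense alleles
(missing entries excluded per feature), loci with no missense allele become
padding, and padding is added *outside* the real loci so the real context
stays contiguous with the target at index 5.  Indel windows follow the same
rules around the directly affected codons: for deletions the target block
is the deleted loci with their missense-averaged profiles; for insertions
the inserted length is filled with the arithmetic mean of the two loci
adjacent to the insertion point ("adjacent" is unquantified in general, so
the symmetric two-locus mean avoids strand bias).  The target block is
left-aligned in a 48-slot region between two 5-slot context blocks (58
total); the left alignment anchors the final timestep — the indel head's
input — on right-context loci.  Indels spanning exon junctions are rejected
with a distinct error rather than guessed.  Coordinates are 1-based
inclusive, VCF-style left-anchored ref/alt; multi-allelic records are split
before windowing; variants overlapping several transcripts are scored once
per transcript rather than collapsed to a canonical one.

## Curation rules

Label resolution partitions assertion sets into TP (⊆ {pathogenic,
likely_pathogenic}), TN (⊆ {benign, likely_benign}), vus_only ({vus}) and
conflicting (any mix across the three sides); the partition is exhaustive
over all 31 nonempty subsets and tested as such.  "Present" in a population
dataset means an AF record exists — AF = 0 with a record still counts as
present — and the SNV training filter keeps variants absent from ≥ 1 and
present in ≥ 1 of {1000GP, ExAC, gnomAD}.  Indel training keeps
non-frameshift events with 1 < length ≤ 48.  Rarity defaults to max AF <
0.01 across datasets.  Matched negatives are drawn one per positive,
uniformly among same-chromosome candidates within 10 kb, without
replacement, in a deterministic positive order; unmatched positives are
reported, not fatal.  The 70/30 split is stratified by label (the
stratification is a package choice; a plain random split would also be
defensible) and deterministic per seed.

## Synthetic data

The generator emulates the statistical shape of a real per-allele
annotation resource: 1–3 alternative alleles per CDS locus with a
configurable synonymous fraction; single- and multi-exon transcripts on
both strands; 24 score features driven by shared per-allele latents with
block correlations in the 0.4–0.85 range (functional and conservation
blocks coupled at 0.6); zero-inflated Beta AF features in which benign
variants are observed more often and at higher frequencies; ~5% missing
scores; ClinVar-like records with controlled rates of likely_* usage,
VUS-only records and deliberate conflicts, with bookkeeping that makes
every expected curation outcome exactly checkable.

Signal geometry: each codon c carries an iid standard-normal latent field
value r_c; all missense alleles in codon c are pathogenic iff r_c exceeds
the (1 − p_pathogenic) quantile (p_pathogenic = 0.35, matching a roughly
1:2 pathogenic:benign curated mix).  An allele's features are shifted by
`effect_size_target · label + effect_size_context · r_{c−1}` — its own
label plus the field value of the *preceding* codon.  Consequently the
downstream flanking codon of a target carries the target's label signal in
its features while the target's own features carry only r of its
neighbour, which is independent of its label.  An earlier symmetric design
(shift by the mean field of both neighbours) was discarded because half the
planted shift is then irreducible nuisance and the recoverable AUC
saturates near 0.85 no matter the effect size.

Three study conditions are fixed as presets and used by the tests and the
acceptance script:

* **default** — effect_size_target 0.8, effect_size_context 0.5, benign
  variants observed with probability 0.7 vs 0.35 for pathogenic: feature
  and AF signal coexist, so AF masking costs a measurable but minor amount
  of AUC (the de novo scenario).
* **context_signal** — effect_size_target 0, effect_size_context 2.0, AF
  decoupled from the label, 75 transcripts so ≥ 5000 curated examples
  survive the training filters: all signal lives in the flanking codons,
  the condition under which the recurrent model demonstrably beats the
  target-only feed-forward ablation.
* **null** — no effect anywhere; the pipeline must sit at AUC ≈ 0.5.

Default scale is 50 transcripts × 100 codons (≈ 25k allele rows, ≈ 15k
labeled missense variants), which keeps every pipeline run in the tests and
the acceptance script to tens of seconds on one CPU; indel runs use a few
hundred codon-aligned deletions (plus-strand transcripts only, for
simplicity of the synthetic ref/alt strings).

What the generator does **not** emulate: real nucleotide sequence and
mutational signatures, the marginal distributions of any named tool's
scores, linkage between nearby variants beyond the codon field, and
database-version effects.  Passing tests therefore demonstrate that the
machinery recovers signal with the planted correlation structure, not that
any particular real-data AUC would be reproduced.

## Hyperparameter search

`hyperparameter_search` minimises validation log loss over GRU width
{16, 32, 64, 128}, depth {1, 2}, dense width {16, 32, 64}, dropout
[0, 0.5], log-uniform learning rate [1e-4, 1e-2] and batch size
{32, 64, 128}.  The first third of the budget (≥ 3 trials) is random; the
remainder fits a Matérn-kernel Gaussian process to completed trials and
picks the expected-improvement maximiser among 64 random candidates.  A
`method="random"` fallback does pure random search.  Both are
deterministic per seed and persist a trial log.

## Numerical choices and degenerate inputs

float64 throughout the network; BCE probabilities clipped at 1e-12;
Glorot-uniform weight initialisation with zero biases, seeded; batch order
and dropout masks drawn from a generator seeded by the training config.
Ties in ROC thresholds are handled by the Mann–Whitney convention (ties
count one half); average precision is the step-wise (non-interpolated)
sum; the 95%-sensitivity threshold uses observed scores only and the weak
inequality (sensitivity ≥ 0.95), so on finite data the reported operating
point always exists.  Single-class score sets, empty allele lists,
zero-variance columns, frameshift lengths, spans > 48 bp and exon-junction
indels all raise typed errors rather than degrade silently.

## Known limitations

The consequence routing in VCF annotation trusts the annotation table and
ref/alt lengths; it performs no sequence-level effect prediction (no splice
or stop-gain calling), and mixed substitution-indel alleles are rejected.
Component scores are consumed, never computed.  The indel generator emits
deletions only, so insertions are exercised by unit tests rather than the
training pipeline.  Reported synthetic AUCs characterise the pipeline under
the planted-signal conditions above and are not estimates of real-data
performance.
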