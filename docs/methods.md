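# Methods

This note documents the models, rules and numerical choices behind each
stage of `neovax`, the defaults of the synthetic-data generators, and what
the test suite does and does not demonstrate about real data.

## Mutated peptide construction

Inputs are CDS-level: each somatic variant carries a 1-based CDS position on
a designated canonical transcript, with VCF-style anchored ref/alt for
indels (the anchor base is included in both alleles). Multi-isoform
expansion is deliberately out of scope — callers supply the canonical
transcript per variant.

Consequences are computed on the mutated CDS: equal-length alleles are
synonymous/nonsense/missense by codon comparison; indels are frameshift
when the length change is not a multiple of 3, otherwise in-frame.
Synonymous and nonsense variants never yield a vaccine candidate.

* **SNV window.** The mutated protein is re-translated and the window of 13
  residues on each side of the changed residue is taken (27mer, mutation
  central). When the mutation lies within 13 residues of a terminus the
  window keeps all available flank and is not padded, so the mutation need
  not be central; length is then in [14, 26]. In-frame indels are windowed
  the same way around the first changed residue — the rule set distinguishes
  only substitution-like and frameshift cases, and an in-frame indel behaves
  locally like a substitution.
* **Frameshift tail.** The mutated CDS is re-translated allowing the shifted
  frame to run to its first stop (or transcript end); the MPS is the novel
  sequence from the first residue differing from the wild-type protein,
  hard-capped at 50 aa. A frameshift whose shifted frame stops immediately
  (no novel residue) is discarded with a logged reason.
* **Germline phasing.** Protein-changing germline SNVs arrive with explicit
  `in_phase_with` flags (read-level phasing happens upstream). Calls in
  phase with a somatic variant and inside its window are applied to the
  emitted sequence and recorded; their positions count as mutated for
  epitope enumeration.

## Epitope enumeration and scoring

Class I enumerates every 8–11mer window of the MPS overlapping ≥ 1 mutated
position, scored against the patient's HLA-A/B/C alleles; class II
enumerates 15mers against HLA-DRB only (DQ/DP are not scored). Scores
follow the percentile-rank convention of consensus binding predictors:
lower is stronger, and the per-MPS "best" is the minimum over that class's
rows. An MPS too short for any 15mer receives the sentinel 999 for class II
so it sorts after every genuine percentile.

Real predictors are external web tools; the shipped `MockPredictor` maps
`sha256(peptide|allele|seed)` uniformly onto [0, 100], giving a
deterministic, configuration-stable stand-in. Planted (peptide, allele)
pairs can be forced to score 0.1 so closed-loop tests know the best score
by construction. Alleles are normalized to `A*02:01`-style strings.

## Prioritization, selection and construct assembly

Stages run in order on the RNA-expressed pool (RNA VAF > 0), each drawing
only from candidates not yet selected, until 46 MPS are reached:

| stage | pool | rank key | cap |
|---|---|---|---|
| s1 | indel MPS | best class I score ↑ | 5 |
| s2 | SNV MPS, ≥ 10 RPKM | best class II score ↑ | 20 |
| s3 | SNV MPS, ≥ 1 RPKM | best class I score ↑ | 20 |
| s4 | SNV MPS | expression ↓ | to 46 |
| s5 | RNA-silent, has class I score | best class I score ↑ | to 46 |
| s6 | RNA-silent, remainder | expression ↓ | to 46 |

Stages s5/s6 exist only as a fallback when the expressed pool cannot fill
46. The split of the fallback into a score-ranked pass and an
expression-ranked pass is this package's reading of a rule stated with two
criteria; candidates with any class I score go through s5, the rest through
s6. Ties everywhere break by (score ascending, RPKM descending, variant id
lexicographic), making the whole procedure a pure function of its inputs.
One consequence of the staged rules as written: expressed indel MPS beyond
the 5 admitted by s1 cannot re-enter later stages (s2–s4 are SNV-only and
the fallback pool is RNA-silent), so the prioritized list can be shorter
than the candidate pool even below 46.

Selection takes the first 20 prioritized MPS by default; an optional
composite re-ranking (weighted best-class-I/II scores, RPKM, DNA VAF) is
available but off by default, and the manual review board of a clinical
workflow is explicitly not modelled. Targets are dealt alternately by rank
onto two strings (≤ 10 each, balanced within one). Each string's ORF is
`SEC ++ t1 ++ L ++ t2 ++ … ++ tn ++ MITD` with a 10-residue glycine/serine
linker (default `GGSGGGGSGG`, 30 nt); SEC (26 aa) and MITD (55 aa) are fixed
literals, so |ORF| = 81 + Σ|tᵢ| + 10(n−1). Nucleotide sequences come from a
fixed most-frequent-human-codon table — deterministic, with
translate(reverse_translate(x)) = x; codon *optimization* is a non-goal.
The FI RNA-stability element and UTR/poly(A) designs belong to the vector
backbone and are carried as construct metadata, not concatenated into the
ORF.

## ELISpot response calling

Replicate-level well counts (duplicates or triplicates; wells flagged "too
numerous to count" imputed at a configurable cap, default 2000) are
compared with the same sample's medium-only control by distribution-free
resampling. The statistic is T = mean(antigen) − R·mean(control) with R = 1
("eq") and R = 2 ("2x").

Numerical scheme: antigen wells are shifted so the null holds exactly in
the empirical distributions, within-group deviations are inflated by
√(n/(n−1)) (the plug-in bootstrap variance understates the sampling
variance by exactly that factor, which is material at n = 2–3), and both
groups are resampled with replacement. When the resample space
n_a^n_a·n_c^n_c ≤ 10⁴ — always true for duplicates and triplicates — it is
enumerated exhaustively and the p-value is exact and seed-free, with
resamples tied with T counted against rejection (p = (#{T* ≥ T} + 1)/(N+1)).
Larger well sets fall back to B seeded Monte Carlo resamples (default
B = 10⁴).

Calibration, measured by simulation with negative-binomial wells (mean 2,
dispersion 5, triplicates): the eq-variant p-values are valid in the
Kolmogorov-band sense (empirical CDF within the α = 0.01 band of the
diagonal over 1000 null pairs) though mildly anticonservative at exactly
α = 0.05 (≈ 0.08) — an intrinsic property of mean-based resampling tests at
three wells per group. The response *call*, which gates on the 2× test by
default, has a null positive rate ≤ 0.015 and, with the count gate, ≈ 0.

A response is positive iff the configured test policy rejects at α = 0.05
**and** the mean antigen count is ≥ 7 spots per well; the count gate is
applied to raw per-well means, not normalized magnitudes. Policies:
`require_2x` (default; the eq p-value is still reported), `require_both`,
`require_any`. No cross-antigen multiplicity correction is applied by
default (calls are reported per antigen); magnitudes are normalized to
spots per 10⁶ effector cells. Pre/post call pairs classify each antigen
(de novo, amplified, pre-existing unchanged, none); the reported fold change
floors the pre-vaccination magnitude at the equivalent of 1 spot per well.
The amplified class is defined by positivity at both timepoints — no fold
threshold is imposed; the fold is reported alongside. The post-IVS arm uses
the simpler rule: positive iff post mean ≥ 2 × pre mean and above the
control-peptide background, with a zero baseline requiring post mean ≥ 7.
Per-patient kinetics sum normalized magnitudes over the de novo + amplified
antigens per timepoint, with absent antigens contributing zero.

## Reverse immunomonitoring

The clonotype identity key is the TRB CDR3 amino-acid sequence alone (V/J
calls are annotations). Enrichment is post-anchored: every clone observed
post-treatment gets a record; clones that contracted to zero are not the
procedure's concern (it exists to pick expanded candidates). De novo clones
(absent pre-treatment) are imputed at the minimum frequency observed in the
pre-treatment repertoire of the same compartment, so their fold is
post-frequency / floor and is non-increasing in the floor. Pre-existing
folds are frequency ratios, invariant to total-count rescaling.

Pairing uses post-treatment single-cell VDJ data: clonotypes must have
exactly one TRB and ≥ 1 TRA (two-TRB doublet artifacts discarded;
multi-TRA clonotypes keep the best-supported TRA as primary). Selection
takes up to 15 de novo and up to 15 pre-existing paired clones by fold
descending (ties: higher post frequency, then CDR3), never borrowing
between classes, total ≤ 30. Reporter specificity is luminescence ≥ 2.0 ×
the TCR's effectors-only control for ≥ 1 (antigen, HLA) condition; the
boundary is inclusive. Tracking emits a clone × sample frequency matrix
(explicit zeros for absence, e.g. in tumour tissue) plus a cumulative row.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`), byte-reproducible, and
emit truth tables sufficient to score every downstream call.

* **Cohort** (`CohortSpec`): 60 transcripts of 120–400 random sense codons
  (ATG-initiated, single terminal stop); log-normal RPKM (log-mean 2.0,
  log-sd 1.5 — median ≈ 7 RPKM, straddling the 1/10 RPKM gates), 10%
  unexpressed; requested consequence counts (default 30 missense, 4
  frameshift, 3 synonymous, 2 nonsense) realized *exactly* by searching
  codons for single-base edits with the desired effect, verified in a
  closed loop against the classifier; beta-distributed DNA/RNA VAFs with
  10% RNA-silent; an 8-allele HLA typing (6 class I + 2 DRB).
* **ELISpot** (`ElispotSimSpec`): negative-binomial wells (baseline mean 2,
  dispersion 5, triplicates, 2 × 10⁵ cells/well) at two timepoints;
  responder antigens gain a 20× multiplicative effect post-vaccination,
  pre-existing antigens are elevated 8× at baseline and further amplified
  post; non-responders share the control distribution.
* **Repertoires** (`RepertoireSimSpec`): 2000 clones with power-law
  (exponent 1.5) base weights, multinomially sampled at depth 3 × 10⁴ pre
  and post (5 × 10³ tumour); 10 de novo spikes (zero pre-treatment weight
  by construction) and 10 pre-existing spikes (drawn from the
  well-sampled decile so they are observed pre), both expanded 100-fold;
  paired-chain probability 0.8; three two-TRB artifacts for the gate to
  discard; a reporter matrix in which exactly the paired spiked clones'
  TCRs exceed the twofold cut-off (specific folds uniform 3–20×,
  non-specific 0.5–1.5×).

The generators emulate the *statistical shape* the pipeline consumes — not
codon usage, HLA frequencies, sequencing error, PCR bias, repertoire
overlap structure, or plate effects. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
models, not performance on clinical data.

## Problem sizes and degenerate inputs

Default verification sizes, chosen to make every statistical claim
measurable while keeping the full suite inside a coffee break: 1000 null
pairs for type-I error, 200 replicates for power, 100 seeded repertoire
replicates (20 spiked clones each) for recovery, 10–20 random instances of
≤ 15 candidates for brute-force equivalence of the staged prioritization.

Degenerate inputs are contracts, not surprises: empty variant lists yield
empty MPS lists; an MPS shorter than 8/15 aa yields no class I/II peptides
(sentinel best score); an empty pre-treatment repertoire is an error (no
imputation floor exists); duplicate wells cannot reach p < 0.05 under exact
enumeration (minimum p = 1/17) — a property of the data, reported honestly
rather than patched; > 20 selected targets, non-G/S linkers, zero reporter
controls, and inconsistent selection caps all raise.

## Known limitations

Single canonical transcript per variant; overlapping somatic variants are
not merged into one MPS (one MPS per variant); class II restricted to DRB;
the DFR eq-variant's mild anticonservatism at α = 0.05 with triplicates
(documented above); no modelling of positive-control wells, inter-plate
normalization, or manual review steps; mock predictor scores carry no
biology beyond determinism and range.
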