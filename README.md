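# neovax

Design and immunomonitoring toolkit for individualized neoantigen mRNA
vaccines.

Personalized cancer vaccines encode a patient's own tumour mutations:
somatic variants are called from tumour/normal sequencing, translated into
mutated peptide sequences (MPS), ranked by predicted HLA presentation and
tumour expression, and the best targets are concatemerized onto mRNA
molecules. After vaccination, T cell induction is read out by IFNγ ELISpot
and by T cell receptor (TCR) repertoire sequencing. `neovax` implements this
computational chain as a tested, reusable library plus CLI, for
immunoinformaticians and assay analysts who need the individual pieces —
peptide windowing, staged target prioritization, construct assembly,
replicate-level response statistics, clonotype enrichment — as callable,
reproducible functions. All analyses run on synthetic or user-supplied
tabular data; sequencing-level steps (alignment, variant calling, MiXCR,
Cell Ranger) are upstream and out of scope, as are real MHC-binding
predictors (a deterministic mock stands behind a pluggable interface).

## What it computes

**Antigen construction.** For a missense SNV at protein position *i*, the
MPS is the window *i* ± 13 (a 27mer with the changed residue central;
truncated at protein termini). For a frameshift indel it is the novel
sequence from the first changed residue to the next stop, capped at 50 aa.
Synonymous and nonsense variants are filtered; in-phase germline variants
inside the window are incorporated.

**Epitope scoring.** All variant-containing 8–11mers (HLA class I, A/B/C)
and 15mers (class II, DRB) of each MPS are scored by a percentile-rank
predictor (lower = stronger); the minimum per class is the MPS's best score.

**Prioritization.** From mutations expressed in tumour RNA (RNA VAF > 0),
staged selection up to 46 MPS: (1) ≤ 5 indel MPS by class I score; (2) ≤ 20
SNV MPS with expression ≥ 10 RPKM by class II score; (3) ≤ 20 SNV MPS with
≥ 1 RPKM by class I score; (4) further SNV MPS by expression; then, only if
short of 46, RNA-silent mutations by class I score and expression. Up to 20
targets are selected and dealt onto two mRNA strings (≤ 10 each), each
assembled as SEC – target₁ – G/S linker (30 nt) – … – targetₙ – MITD with a
fixed human-codon reverse translation, so |ORF| = 81 + Σ|tᵢ| + 10(n−1)
residues.

**ELISpot response calling.** Antigen wells vs medium-only wells are
compared by distribution-free resampling (DFR): a one-sided bootstrap test
of H0: mean(antigen) ≤ R·mean(control), R = 1 and R = 2, exact-enumerated
for duplicate/triplicate wells. A response is positive when p < 0.05 (2×
test, by default) and the mean antigen count is ≥ 7 spots/well; pre/post
comparison classifies antigens as de novo, amplified, pre-existing
unchanged, or none. Magnitudes are reported as spots per 10⁶ cells; the
post-IVS arm uses the ≥ 2-fold increase rule.

**Reverse immunomonitoring (RevImMo).** Bulk TRB clonotypes with identical
CDR3 amino-acid sequence are merged; post/pre frequency ratios rank clonal
enrichment, with clones undetected pre-treatment imputed at the lowest
pre-repertoire frequency. Only clonotypes with paired TRA/TRB single-cell
evidence (two-TRB clonotypes discarded) are eligible; up to 15 de novo and
15 pre-existing clones (≤ 30 total) are selected for cloning. Reporter
luminescence ≥ 2-fold over the effectors-only control calls a TCR specific,
and specific clones are tracked across timepoints and tissue by TRB CDR3.

## Worked example

Generate a synthetic patient and run the three analyses:

```
$ neovax simulate --kind all --seed 1 --out fixture
$ neovax design --transcripts-fasta fixture/P01_transcripts.fasta \
    --transcripts-tsv fixture/P01_transcripts.tsv \
    --variants fixture/P01_variants.tsv --germline fixture/P01_germline.tsv \
    --hla fixture/P01_hla.tsv --patient-id P01 --seed 1 --out design
$ neovax elispot --input fixture/elispot.tsv --out monitoring
$ neovax revimmo --pre fixture/repertoire_pre.tsv --post fixture/repertoire_post.tsv \
    --tumour fixture/repertoire_tumour.tsv --sc fixture/single_cell.tsv \
    --luminescence fixture/luminescence.tsv --out revimmo
```

The design manifest reports 34 prioritized MPS (the seed-1 cohort has 39
variants, of which 5 are synonymous/nonsense and filtered) and 20 selected
targets split 10 + 10 over two strings with ORFs of 1428 and 1257 nt. The
target table carries full provenance:

```
 rank      mps_id  string       kind selection_step  best_class1  best_class2      rpkm
    1 MPS_VAR0036       1 frameshift  s1_indel_hla1     0.019420     2.923310  1.906603
    2 MPS_VAR0038       2 frameshift  s1_indel_hla1     0.089907     3.131316  0.000000
    3 MPS_VAR0037       1 frameshift  s1_indel_hla1     0.276428     0.024738 47.017986
```

(rank = prioritization order; `best_class1`/`best_class2` are the best
percentile-rank binding scores, lower = stronger; indel MPS enter first via
the class-I-ranked indel stage.)

ELISpot classification on the simulated wells recovers the planted truth —
6 de novo responses, 1 amplified, 13 none — and the kinetics sum over
immunogenic antigens rises from 103 to 2678 spots per 10⁶ cells after
vaccination. The RevImMo run selects 30 candidates (15 de novo +
15 pre-existing, all with paired chains); the top candidate expanded
190-fold (pre frequency 3.3 × 10⁻⁵ → post 6.3 × 10⁻³), and 16 of 20 tested
TCRs call specific at the twofold reporter cut-off — exactly the spiked,
paired clones.

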