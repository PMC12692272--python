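# Default scoring rules for isoform-aware CRB1 variant impact estimation.
# Every constant used by the scoring engine lives here; the engine refuses
# to run without a config and echoes the effective values into its reports.

allele_share: 50.0            # percentage points of total expression per allele

# Fraction of an allele's output retained per consequence class.
expression_retention:
  truncating: 0.0             # nonsense / frameshift: no product
  splice_site: 0.05           # canonical +1..+3 sites keep ~5% wild-type transcript
  missense: 1.0               # single-residue substitutions do not change mRNA level
  in_frame: 1.0               # in-frame deletions/duplications keep expression

in_frame_fraction: 0.2        # pathogenic fraction assigned to an in-frame indel

# Missense pathogenic fraction by number of damaging in-silico predictors
# (15 predictors consulted in total). Counts below the lowest bin score 0;
# counts above the top bin clamp to the top value (both warn).
damaging_bins:
  - [6, 10, 0.5]
  - [11, 12, 0.7]
  - [13, 14, 0.8]

splice_tool_unit: 0.2         # pathogenic fraction per splice-prediction tool (of 4)

combine_rule: additive_clamped   # additive_clamped | multiplicative
total_rule: mean_over_three_isoforms   # mean_over_three_isoforms | sum_over_affected
splice_residual_mode: allele_fraction  # allele_fraction (5% of the allele) | absolute_points

# Phenotype classification thresholds (percent).
lca_a_loss_threshold: 85.0    # CRB1-A pathogenicity at/above this -> LCA
cd_total_threshold: 50.0      # total pathogenicity at/above this -> CRD, below -> CD

# Exon membership of the three CRB1 transcripts, canonical 12-exon numbering.
# Exon 6 is the only exon shared by all three; A spans every exon.
isoform_model:
  A: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
  B: [6, 7, 8, 9, 10, 11, 12]
  C: [1, 2, 3, 4, 5, 6]
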