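# Published pilot comparison of curated (UniProtKB/Swiss-Prot-style)
# versus submission-based (ClinVar-style, 2-star) interpretations of 4286
# shared missense variants (December 2017 releases), plus the re-curation
# outcomes of two random 100-variant samples.
#
# Rows: curated-resource bucket (disease, polymorphism, unclassified).
# Columns: harmonized repository bucket, or the re-curated bucket for the
# two transition tables, in the same order.
buckets: [disease, polymorphism, unclassified]
global_comparison:
  counts:
    - [1328, 111, 94]
    - [46, 2328, 128]
    - [55, 81, 115]
recuration_discordant:
  # 100 variants whose interpretations disagreed before re-curation
  counts:
    - [1, 31, 20]
    - [6, 4, 8]
    - [4, 16, 10]
  solved_conflicts: 78
  modified_without_agreement: 7
  retained: 15
recuration_concordant:
  # 100 variants whose interpretations agreed before re-curation
  counts:
    - [54, 0, 4]
    - [0, 38, 0]
    - [0, 0, 4]
  confirmed: 96
  modified: 4
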