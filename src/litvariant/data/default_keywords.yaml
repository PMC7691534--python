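# Built-in mechanism/context keyword categories.  Terms are matched
# case-insensitively on word boundaries; multi-word terms are allowed.
# Fully overridable by user-supplied keyword rows.
mutation:
  - mutation
  - mutations
  - mutated
  - variant
  - variants
  - substitution
  - missense
  - nonsense
  - frameshift
  - indel
  - polymorphism
cnv:
  - copy number
  - copy-number
  - deletion
  - deletions
  - deleted
  - amplification
  - amplified
  - duplication
  - microdeletion
  - microduplication
fusion:
  - fusion
  - fusions
  - rearrangement
  - rearrangements
  - translocation
  - translocations
  - chimeric
  - chimera
expression:
  - expression
  - overexpression
  - overexpressed
  - upregulation
  - upregulated
  - downregulation
  - downregulated
cancer:
  - cancer
  - cancers
  - tumor
  - tumour
  - carcinoma
  - leukemia
  - leukaemia
  - lymphoma
  - sarcoma
  - melanoma
  - malignant
  - malignancy
  - oncogenic
  - metastatic
deletion_amplification:
  - deletion
  - deletions
  - deleted
  - microdeletion
  - amplification
  - amplified
  - duplication
  - duplicated
  - copy number loss
  - copy number gain
  - homozygous deletion
  - hemizygous deletion
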