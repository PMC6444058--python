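# Evidence profiles for the two worked re-curation examples.
#
# GLI3 p.Ile808Met / Greig cephalopolysyndactyly syndrome (GCPS):
# population frequency (~0.2% in ExAC and gnomAD) vastly exceeds the
# maximum credible frequency for a dominant disease with prevalence
# ~1/1,000,000, so BS1 applies at full (strong) weight; healthy adult
# carriers give BS2, down-weighted to supporting because GCPS penetrance
# is below 100%; the in vitro assay lacks a mechanistic link to the
# disease and is disregarded. Expected call: Likely benign.
#
# ATP7B p.Met645Arg / Wilson disease (WD): frequency 0.05% in ExAC lies
# well below the carrier allele frequency (carrier frequency 1.1% = 1/90)
# with no homozygote reported, giving PM2; the variant is repeatedly found
# in trans with pathogenic variants in WD patients (PM3, supplied); copper
# transport assays show wild-type-like activity (BS3). Expected call:
# Uncertain significance with conflicting evidence.
- variant: "GLI3 P10071 p.Ile808Met (NM_000168.5:c.2424A>G)"
  disease:
    name: "Greig cephalopolysyndactyly syndrome"
    omim_id: "175700"
    inheritance: autosomal_dominant
    prevalence: 1.0e-06
    penetrance: 1.0
    is_mendelian: true
  observations:
    - dataset: "ExAC r0.3"
      allele_frequency: 0.002
      homozygote_count: 0
      healthy_adult_observed: true
    - dataset: "gnomAD r2.0"
      allele_frequency: 0.002
      homozygote_count: 0
      healthy_adult_observed: true
  assays:
    - effect: damaging
      reflects_biology: false
      description: >-
        In vitro reduction of nuclear localization and transcriptional
        activity, with no established link to Hedgehog signalling in vivo;
        disregarded.
  adjustments:
    - code: BS2
      strength: supporting
      justification: "GCPS penetrance is below 100%"
- variant: "ATP7B P35670 p.Met645Arg (NM_000053.3:c.1934T>G)"
  disease:
    name: "Wilson disease"
    omim_id: "277900"
    inheritance: autosomal_recessive
    prevalence: 3.3333e-05
    penetrance: 1.0
    carrier_frequency: 0.0111
    is_mendelian: true
  observations:
    - dataset: "ExAC r0.3"
      allele_frequency: 0.0005
      homozygote_count: 0
      healthy_adult_observed: false
    - dataset: "gnomAD r2.0"
      allele_frequency: 0.0005
      homozygote_count: 0
      healthy_adult_observed: false
  assays:
    - effect: no_effect
      reflects_biology: true
      description: >-
        Copper transport activity comparable to wild type in vitro and in
        vivo.
  supplied:
    - code: PM3
      justification: >-
        Repeatedly detected in trans with a pathogenic variant in Wilson
        disease patients.
      source: "literature reports"
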