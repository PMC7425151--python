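# Default code lists for the four procedure / primary-indication combinations.
#
# Entries are given in display form (ICD-10-CM with dots); they are normalized
# (uppercased, dots stripped) on load.  A trailing asterisk on an ICD-10 entry
# marks a hierarchical pattern: every child code sharing the stem's prefix in
# the dot-free ICD-10 hierarchy also matches.  CPT entries are exact
# five-character codes and never carry wildcards.
#
# Other institutions can adapt these lists without touching the engine; run
# `orthoclaims codebook lint <file>` to validate an edited copy.

spine_age_threshold_years: 50
inclusion_hierarchy: false

combinations:
  - id: SPS
    label: "Spinal surgery for lumbar spinal stenosis"
    panel: spine
    inclusion_cpt:
      ["22224", "22533", "22558", "22586", "22612", "22614", "22630",
       "22632", "22633", "22800", "22802", "22804", "22808", "22810",
       "22857", "22862", "22867", "63005", "63011", "63012", "63017",
       "63047", "63048", "63056", "63087", "63088", "63090", "63091",
       "63102", "63103", "63170"]
    inclusion_icd:
      ["M48.00", "M48.061", "M48.062", "M48.07", "M48.08"]
    exclusion_icd:
      ["G83.4", "R15*", "S32.0*", "N31*", "C41.2", "M48.56*", "M84.58*",
       "R32", "M48.46*", "M84.48*", "M84.40*", "M84.60*", "M48.57*",
       "S22.08*"]

  - id: HD
    label: "Spinal surgery for lumbar herniated disc"
    panel: spine
    inclusion_cpt:
      ["22224", "22533", "22558", "22586", "22612", "22614", "22630",
       "22632", "22633", "22800", "22802", "22804", "22808", "22810",
       "22857", "22862", "22867", "62287", "63005", "63011", "63012",
       "63017", "63030", "63035", "63042", "63047", "63048", "63056",
       "63087", "63088", "63090", "63091", "63102", "63103", "63170"]
    inclusion_icd:
      ["M51.06", "M51.16", "M51.17", "M51.26", "M51.27", "M51.36",
       "M51.37", "M47.16", "M47.26", "M47.27"]
    exclusion_icd:
      ["G83.4", "R15*", "S32.0*", "N31*", "C41.2", "M48.56*", "M84.58*",
       "R32", "M48.46*", "M84.48*", "M84.40*", "M84.60*", "M48.57*",
       "S22.08*"]

  - id: HOA
    label: "Hip arthroplasty for hip osteoarthritis"
    panel: hip_knee
    inclusion_cpt:
      ["27125", "27130", "27132"]
    inclusion_icd:
      ["M16.0", "M16.10", "M16.11", "M16.12", "M16.2", "M16.30",
       "M16.31", "M16.32", "M16.4", "M16.50", "M16.51", "M16.52",
       "M16.6", "M16.7", "M16.9"]
    exclusion_icd:
      ["M84.459*", "M84.559*", "S72.0*", "S32.4*", "M87*", "M80*",
       "M84.359*", "M84.58*", "S72.1*", "S72.2*", "C79.51", "M84.30*",
       "M84.40*", "M84.48*", "M84.50*", "C41.4", "C41.9"]

  - id: KOA
    label: "Knee arthroplasty for knee osteoarthritis"
    panel: hip_knee
    inclusion_cpt:
      ["27438", "27440", "27441", "27442", "27443", "27445", "27446",
       "27447"]
    inclusion_icd:
      ["M17.0", "M17.10", "M17.11", "M17.12", "M17.2", "M17.30",
       "M17.31", "M17.32", "M17.4", "M17.5", "M17.9"]
    exclusion_icd:
      ["M80*", "M87*", "C79.51", "C41.9"]
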