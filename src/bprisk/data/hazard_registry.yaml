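# Toxicological reference points for benzophenone-type photoinitiators.
#
# Each analyte block lists one or more hazard profiles (a point of departure
# with its critical endpoint and the margin-of-exposure target that applies
# to it).  Exactly one profile per analyte is marked `primary: true`; that
# profile anchors the MOE verdict and the cumulative MOE_T.  Analytes lacking
# animal toxicity data carry `ttc_only: true` with a Cramer structural class
# and are screened against the threshold of toxicological concern instead.
analytes:
  BP:
    profiles:
      - pod_type: TDI
        pod_value: 0.03
        endpoint: nonneoplastic kidney effects (chronic rat study; UF 100)
        endpoint_class: noncarcinogen
        target_moe: 1
        source: EFSA 2009 tolerable daily intake
      - pod_type: BMDL10
        pod_value: 3.1
        endpoint: nonneoplastic kidney effects
        endpoint_class: noncarcinogen
        target_moe: 100
        source: EFSA benchmark-dose analysis, lower end of 3.1-7.4 band
        primary: true
      - pod_type: BMDL10
        pod_value: 18.5
        endpoint: neoplastic kidney lesions (threshold carcinogen)
        endpoint_class: carcinogen
        target_moe: 100
        source: EFSA benchmark-dose analysis
    metadata:
      # Group TDI proposed for BP together with 4-OHBP; informational only,
      # not used in the assessment (supporting data judged insufficient).
      group_tdi_mg_kg_bw_day: 0.01
  4-MBP:
    profiles:
      - pod_type: BMDL10
        pod_value: 3.1
        endpoint: nonneoplastic kidney effects (read-across from benzophenone)
        endpoint_class: noncarcinogen
        target_moe: 200
        source: EFSA; two additional uncertainty factors raise the target MOE
        primary: true
  M2BB:
    profiles:
      - pod_type: NOAEL
        pod_value: 31.25
        endpoint: kidney degeneration and hyperplasia (28-day repeated dose)
        endpoint_class: noncarcinogen
        target_moe: 100
        source: ECHA
        primary: true
  PBZ:
    profiles:
      - pod_type: NOAEL
        pod_value: 300
        endpoint: implantation-site effects (28-day repeated dose)
        endpoint_class: noncarcinogen
        target_moe: 100
        source: 28-day repeated-dose toxicity study
        primary: true
  4-OHBP:
    profiles:
      - pod_type: NOAEL
        pod_value: 100
        endpoint: 28-day repeated-dose toxicity
        endpoint_class: noncarcinogen
        target_moe: 100
        source: 28-day repeated-dose toxicity study
        primary: true
  2-OHBP:
    ttc_only: true
    cramer_class: III

ttc:
  default_bw_kg: 60
  thresholds_ug_person_day:
    I: 1800
    II: 540
    III: 90
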