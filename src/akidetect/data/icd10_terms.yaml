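# Dictionary mapping free-text diagnosis phrases (German and English) to the
# 14 AKI-related ICD-10 comorbidity codes, plus the documented-AKI marker.
# Patterns are case-insensitive regular expressions; "guards" veto a match
# when any guard pattern occurs anywhere in the text.
codes:
  I25:
    label: Chronic ischaemic heart disease
    patterns:
      - "chronisch\\w* isch(ä|ae)misch\\w* herzkrankheit"
      - "chronic isch(a?e)mic heart disease"
      - "isch(a?e)mic heart disease"
      - "koronare herzkrankheit"
      - "\\bKHK\\b"
  I10:
    label: Essential (primary) hypertension
    patterns:
      - "essentielle\\w* hypertonie"
      - "essential (primary )?hypertension"
      - "arterielle\\w* hypertonie"
      - "bluthochdruck"
  E78:
    label: Disorders of lipoprotein metabolism and other lipidaemias
    patterns:
      - "lipid(ä|ae)mie"
      - "lipoprotein"
      - "hypercholesterin"
      - "dyslipid"
      - "hyperlipid"
  E14:
    label: Unspecified diabetes mellitus
    patterns:
      - "diabetes"
  I35:
    label: Nonrheumatic aortic valve disorders
    patterns:
      - "aortenklappenstenose"
      - "aortic valve stenosis"
      - "nonrheumatic aortic valve"
      - "aortenstenose"
  I34:
    label: Nonrheumatic mitral valve disorders
    patterns:
      - "mitralklappen(insuffizienz|stenose|fehler)"
      - "mitral valve (disorder|insufficiency|regurgitation|stenosis)"
      - "mitralinsuffizienz"
  I48:
    label: Atrial fibrillation and flutter
    patterns:
      - "vorhofflimmern"
      - "vorhofflattern"
      - "atrial fibrillation"
      - "atrial flutter"
  N18:
    label: Chronic kidney disease
    patterns:
      - "chronisch\\w* nieren(krankheit|insuffizienz|versagen)"
      - "chronic kidney disease"
      - "chronic renal (failure|insufficiency)"
      - "\\bCKD\\b"
  E66:
    label: Obesity
    patterns:
      - "adipositas"
      - "obesity"
  I70:
    label: Atherosclerosis
    patterns:
      - "atherosklerose"
      - "arteriosklerose"
      - "atherosclerosis"
  J44:
    label: Other chronic obstructive pulmonary disease
    patterns:
      - "\\bCOPD\\b"
      - "chronisch\\w* obstruktive\\w* lungen(krankheit|erkrankung)"
      - "chronic obstructive pulmonary"
  G47:
    label: Sleep disorders
    patterns:
      - "schlafst(ö|oe)rung"
      - "schlafapnoe"
      - "sleep disorder"
      - "sleep apn(o?e)a"
  I33:
    label: Acute and subacute endocarditis
    patterns:
      - "endokarditis"
      - "endocarditis"
  I71:
    label: Aortic aneurysm and dissection
    patterns:
      - "aortenaneurysma"
      - "aortendissektion"
      - "aortic aneurysm"
      - "aortic dissection"
  AKI_DOC:
    label: Documented acute kidney injury
    patterns:
      - "akute\\w* nierenversagen"
      - "akute\\w* nierensch(ä|ae)digung"
      - "acute kidney injury"
      - "acute renal failure"
      - pattern: "\\bAKI\\b"
        # the bare abbreviation is vetoed in valve context: clinicians use
        # "AKI" informally for Aortenklappeninsuffizienz (aortic regurgitation)
        guards:
          - "klappe"
          - "valve"
          - "insuffizienz"
          - "regurgitation"
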