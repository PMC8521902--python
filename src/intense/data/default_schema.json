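{
  "factors": [
    {"name": "age", "kind": "continuous", "units": "years", "label": "Age"},
    {"name": "parity", "kind": "binary", "level_order": ["nulliparous", "parous"], "label": "Parity"},
    {"name": "ethnicity", "kind": "binary", "level_order": ["other", "caucasian"], "label": "Ethnicity"},
    {"name": "bmi", "kind": "continuous", "units": "kg/m^2", "label": "Body mass index"},
    {"name": "endometriosis", "kind": "ordinal3", "level_order": ["absent", "suspected", "confirmed"], "label": "Endometriosis"},
    {"name": "ibs", "kind": "binary", "level_order": ["absent", "present"], "label": "Irritable bowel syndrome"},
    {"name": "pbs", "kind": "binary", "level_order": ["absent", "present"], "label": "Painful bladder syndrome"},
    {"name": "pelvic_floor_tenderness", "kind": "binary", "level_order": ["absent", "present"], "label": "Pelvic floor tenderness"},
    {"name": "abdominal_wall_pain", "kind": "binary", "level_order": ["absent", "present"], "label": "Abdominal wall pain"},
    {"name": "depression", "kind": "continuous", "units": "PHQ-9 score (0-27)", "label": "Depression score"},
    {"name": "anxiety", "kind": "continuous", "units": "GAD-7 score (0-21)", "label": "Anxiety score"},
    {"name": "pain_catastrophizing", "kind": "continuous", "units": "PCS score (0-52)", "label": "Pain Catastrophizing Scale"},
    {"name": "family_history_pain", "kind": "ordinal3", "level_order": ["no", "do_not_know", "yes"], "label": "Family history of chronic pain"},
    {"name": "referral_type", "kind": "binary", "level_order": ["new", "re_referral"], "label": "Referral type"},
    {"name": "age_first_pain", "kind": "continuous", "units": "years", "label": "Age when first experienced pain"},
    {"name": "pain_duration", "kind": "continuous", "units": "years", "label": "Pain duration"},
    {"name": "surgery_helpful", "kind": "ordinal3", "level_order": ["no_prior_surgery", "no", "yes"], "label": "Prior surgery helpful for pain"},
    {"name": "infertility", "kind": "ordinal3", "level_order": ["never_tried", "no", "yes"], "label": "Infertility"},
    {"name": "smoking", "kind": "binary", "level_order": ["no", "yes"], "label": "Smoking"},
    {"name": "alcohol", "kind": "continuous", "units": "drinks/week", "label": "Alcohol use"},
    {"name": "trauma", "kind": "continuous", "units": "score (0-7)", "label": "Trauma"},
    {"name": "dysmenorrhea", "kind": "continuous", "units": "rating (0-10)", "label": "Dysmenorrhea"},
    {"name": "deep_dyspareunia", "kind": "continuous", "units": "rating (0-10)", "label": "Deep dyspareunia"},
    {"name": "cpp", "kind": "continuous", "units": "rating (0-10)", "label": "Chronic pelvic pain"},
    {"name": "ehp30", "kind": "continuous", "units": "score (0-100)", "label": "Endometriosis Health Profile-30"}
  ]
}
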