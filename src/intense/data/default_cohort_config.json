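{
  "n_subjects": 656,
  "marginals": {
    "age": {"mean": 34.5, "sd": 7.6},
    "parity": {"probs": [0.49, 0.51]},
    "ethnicity": {"probs": [0.26, 0.74]},
    "bmi": {"mean": 25.3, "sd": 5.7},
    "endometriosis": {"probs": [0.23, 0.2, 0.57]},
    "ibs": {"probs": [0.47, 0.53]},
    "pbs": {"probs": [0.57, 0.43]},
    "pelvic_floor_tenderness": {"probs": [0.5, 0.5]},
    "abdominal_wall_pain": {"probs": [0.73, 0.27]},
    "depression": {"mean": 9.0, "sd": 6.0, "lower": 0.0, "upper": 27.0},
    "anxiety": {"mean": 8.0, "sd": 5.5, "lower": 0.0, "upper": 21.0},
    "pain_catastrophizing": {"mean": 20.0, "sd": 12.0, "lower": 0.0, "upper": 52.0},
    "family_history_pain": {"probs": [0.45, 0.15, 0.4]},
    "referral_type": {"probs": [0.65, 0.35]},
    "age_first_pain": {"mean": 24.0, "sd": 8.0, "lower": 8.0, "upper": 50.0},
    "pain_duration": {"mean": 9.0, "sd": 7.0, "lower": 0.5, "upper": 40.0},
    "surgery_helpful": {"probs": [0.4, 0.25, 0.35]},
    "infertility": {"probs": [0.35, 0.45, 0.2]},
    "smoking": {"probs": [0.8, 0.2]},
    "alcohol": {"mean": 2.5, "sd": 3.0, "lower": 0.0, "upper": 30.0},
    "trauma": {"mean": 1.5, "sd": 1.8, "lower": 0.0, "upper": 7.0},
    "dysmenorrhea": {"mean": 6.5, "sd": 2.8, "lower": 0.0, "upper": 10.0},
    "deep_dyspareunia": {"mean": 5.0, "sd": 3.2, "lower": 0.0, "upper": 10.0},
    "cpp": {"mean": 5.5, "sd": 2.9, "lower": 0.0, "upper": 10.0},
    "ehp30": {"mean": 45.0, "sd": 22.0, "lower": 0.0, "upper": 100.0}
  },
  "blocks": [
    {"name": "psychological", "factors": ["cpp", "ehp30", "depression", "anxiety", "pain_catastrophizing"], "r": 0.6},
    {"name": "reproductive", "factors": ["age", "parity", "age_first_pain", "infertility"], "r": 0.6, "signs": {"infertility": -1}},
    {"name": "endometriosis_course", "factors": ["endometriosis", "pain_duration"], "r": 0.6},
    {"name": "lifestyle", "factors": ["bmi", "trauma", "smoking"], "r": 0.6},
    {"name": "musculoskeletal", "factors": ["abdominal_wall_pain", "pelvic_floor_tenderness", "deep_dyspareunia"], "r": 0.6}
  ]
}
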