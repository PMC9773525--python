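[
  {
    "name": "breathing-case-proposed",
    "self_report": ["difficulty in breathing"],
    "queries": [
      ["shortness of breath", true],
      ["vomiting", true],
      ["nausea", false],
      ["cough", false]
    ],
    "true_disease": "fluid overload",
    "predicted_disease": "fluid overload"
  },
  {
    "name": "breathing-case-baseline",
    "self_report": ["difficulty in breathing"],
    "queries": [
      ["shortness of breath", true],
      ["skin rash", false],
      ["vomiting", true],
      ["abnormal appearing skin", false]
    ],
    "true_disease": "fluid overload",
    "predicted_disease": "fluid overload"
  },
  {
    "name": "case-13947-baseline",
    "self_report": ["arm pain"],
    "queries": [
      ["neck pain", true],
      ["skin itching", false],
      ["skin lesion", false],
      ["skin rash", false],
      ["eye pain", false],
      ["anxiety and nervousness", false],
      ["facial pain", false],
      ["leg pain", false]
    ],
    "true_disease": "carpal tunnel syndrome",
    "predicted_disease": "adhesive capsulitis of the shoulder"
  },
  {
    "name": "case-13947-hierarchical",
    "self_report": ["arm pain"],
    "queries": [
      ["ache all over", false],
      ["neck pain", true],
      ["headache", false],
      ["back pain", false],
      ["loss of sensation", true],
      ["paresthesia", false],
      ["leg pain", false]
    ],
    "true_disease": "carpal tunnel syndrome",
    "predicted_disease": "carpal tunnel syndrome"
  },
  {
    "name": "case-22285-baseline",
    "self_report": ["wrist pain"],
    "queries": [
      ["hand or finger pain", false],
      ["lower body pain", false],
      ["lower back pain", false],
      ["pain during pregnancy", true],
      ["excessive urination at night", false],
      ["facial pain", true],
      ["skin lesion", false],
      ["abnormal appearing skin", false]
    ],
    "true_disease": "gas gangrene",
    "predicted_disease": "chancroid"
  },
  {
    "name": "case-22285-hierarchical",
    "self_report": ["wrist pain"],
    "queries": [
      ["pain during pregnancy", true],
      ["facial pain", true],
      ["eye pain", false],
      ["excessive urination at night", false],
      ["shoulder cramps or spasms", false],
      ["sharp abdominal pain", true]
    ],
    "true_disease": "gas gangrene",
    "predicted_disease": "gas gangrene"
  }
]
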