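{
  "valueSets": {
    "refsem.Severity": ["severe", "moderate", "slight", "unmarked"],
    "refsem.Course": ["changed", "increased", "decreased", "improved", "worsened", "resolved", "unmarked"],
    "refsem.BodySide": ["left", "right", "bilateral"],
    "refsem.BodyLaterality": ["medial", "lateral", "distal", "proximal", "superior", "inferior", "unmarked"]
  },
  "featureDomains": {
    "polarity": [-1, 1],
    "uncertainty": [0, 1]
  },
  "unitIntervalFeatures": ["confidence", "score"],
  "patterns": {
    "cui": "^C\\d{7}$",
    "tui": "^T\\d{3}$",
    "card": "^\\d+-(\\d+|M)$"
  },
  "defaults": {
    "polarity": 1,
    "uncertainty": 0,
    "conditional": false,
    "generic": false,
    "subject": "patient"
  },
  "typeIdCodes": {
    "0": null,
    "1": "refsem.Medication",
    "2": "refsem.DiseaseDisorder",
    "3": "refsem.SignSymptom",
    "4": "refsem.Lab",
    "5": "refsem.Procedure",
    "6": "refsem.AnatomicalSite"
  },
  "relationCategories": {
    "temporal": ["startTime", "TIMEX-of"],
    "coreference": ["coreference"],
    "lifted": {
      "degreeOf": "relation.DegreeOf",
      "affects": "relation.Affects",
      "locationOf": "relation.LocationOf",
      "resultOf": "relation.ResultOf",
      "manifestationOf": "relation.ManifestationOf"
    }
  },
  "cemModels": {
    "refsem.SignSymptom": "sign_symptom.xml",
    "refsem.AnatomicalSite": "anatomical_site.xml",
    "refsem.DiseaseDisorder": "disease_disorder.xml",
    "refsem.Lab": "lab.xml",
    "refsem.Medication": "medication.xml",
    "refsem.Procedure": "procedure.xml"
  }
}
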