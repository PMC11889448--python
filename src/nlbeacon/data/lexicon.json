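{
  "version": "synthetic-fixture-1.0",
  "terms": {
    "parkinsons disease": [
      {"curie": "SNOMED:49049000", "label": "Parkinson's disease"}
    ],
    "parkinson disease": [
      {"curie": "SNOMED:49049000", "label": "Parkinson's disease"}
    ],
    "alzheimers disease": [
      {"curie": "SNOMED:26929004", "label": "Alzheimer's disease"}
    ],
    "huntingtons disease": [
      {"curie": "SNOMED:58756001", "label": "Huntington's chorea"}
    ],
    "epilepsy": [
      {"curie": "SNOMED:84757009", "label": "Epilepsy"}
    ],
    "migraine": [
      {"curie": "SNOMED:37796009", "label": "Migraine"}
    ],
    "dystonia": [
      {"curie": "SNOMED:15802004", "label": "Dystonia"}
    ],
    "diabetes": [
      {"curie": "SNOMED:46635009", "label": "Diabetes mellitus type 1"},
      {"curie": "SNOMED:44054006", "label": "Diabetes mellitus type 2"}
    ]
  }
}
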