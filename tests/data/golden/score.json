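{
  "chi_squared": 12.093984200670233,
  "df": 1,
  "asymptotic_p": 0.0005058476622104978,
  "n_permutations": 1000,
  "n_as_extreme": 1,
  "empirical_p": 0.001998001998001998,
  "classification_score": 2.6994040818153375,
  "seed": 1
}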