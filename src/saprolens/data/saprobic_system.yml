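# Saprobic system configuration: code valences and classification bands.
#
# Valences follow the standard Pantle-Buck scale (oligosaprobic = 1.0 ...
# polysaprobic = 4.0) with transitional codes at the midpoint of their
# endpoints. The source community table names its codes but not their
# numeric values, so these are generic literature valences; species-level
# overrides may be supplied under `species_overrides`.
#
# `p-i` (a poly-leaning transitional form) and `p-m` (polysaprobic to
# mesosaprobic) are mapped to 3.5; both are deliberate, overridable choices.
valences:
  o: 1.0
  o-b: 1.5
  b: 2.0
  b-a: 2.5
  a-b: 2.5
  a: 3.0
  a-p: 3.5
  p-a: 3.5
  p: 4.0
  o-a: 2.0
  p-i: 3.5
  p-m: 3.5
species_overrides: {}
# Half-open bands [lower, upper) covering [1.0, 4.0).
class_bands:
  - [1.0, 1.5, "Oligosaprobic", "Non-polluted", "I"]
  - [1.5, 1.8, "Oligosaprobic to beta-Mesosaprobic", "Waters without organic load", "I-II"]
  - [1.8, 2.3, "beta-Mesosaprobic", "Waters with a moderate organic load", "II"]
  - [2.3, 2.7, "beta-Mesosaprobic to alpha-Mesosaprobic", "Waters with critical organic load", "II-III"]
  - [2.7, 3.2, "alpha-Mesosaprobic", "Waters strongly polluted", "III"]
  - [3.2, 3.5, "alpha-Mesosaprobic to polysaprobic", "Waters are very strongly polluted", "III-IV"]
  - [3.5, 4.0, "Polysaprobic", "Waters exceptionally polluted", "IV"]
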