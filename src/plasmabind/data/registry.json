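[
  {"id": "2c", "formula": "C15H14ClN3O2", "reported_mh": 304.0847, "r": "3-chlorophenyl", "r1": null, "stage": "pyridazine-1,4-dione intermediate"},
  {"id": "3c", "formula": "C18H18ClN3O4", "reported_mh": 376.1059, "r": "3-chlorophenyl", "r1": null, "stage": "oxyacetate ester intermediate"},
  {"id": "4c", "formula": "C17H18ClN5O3", "reported_mh": 376.1171, "r": "3-chlorophenyl", "r1": null, "stage": "acetohydrazide intermediate"},
  {"id": "5a", "formula": "C22H27N5O3", "reported_mh": 410.2187, "r": "n-butyl", "r1": "H", "stage": "final"},
  {"id": "5b", "formula": "C22H27N5O4", "reported_mh": 426.2136, "r": "n-butyl", "r1": "2-OH", "stage": "final"},
  {"id": "5c", "formula": "C23H29N5O3", "reported_mh": 424.2343, "r": "n-butyl", "r1": "4-CH3", "stage": "final"},
  {"id": "6a", "formula": "C24H23N5O3", "reported_mh": 430.1874, "r": "phenyl", "r1": "H", "stage": "final"},
  {"id": "6b", "formula": "C24H23N5O4", "reported_mh": 446.1823, "r": "phenyl", "r1": "2-OH", "stage": "final"},
  {"id": "6c", "formula": "C25H25N5O3", "reported_mh": 444.2030, "r": "phenyl", "r1": "4-CH3", "stage": "final"},
  {"id": "7a", "formula": "C24H22ClN5O3", "reported_mh": 464.1484, "r": "3-chlorophenyl", "r1": "H", "stage": "final"},
  {"id": "7b", "formula": "C24H22ClN5O4", "reported_mh": 480.1433, "r": "3-chlorophenyl", "r1": "2-OH", "stage": "final"},
  {"id": "7c", "formula": "C25H24ClN5O3", "reported_mh": 478.1640, "r": "3-chlorophenyl", "r1": "4-CH3", "stage": "final"}
]
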