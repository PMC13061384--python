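{
  "cpo_ic50_uM": 1.0,
  "malo_ic50_uM": 13.6,
  "cpo_malo_ratio": 0.007,
  "note": "In vitro oxon mixture parameters as stated in the source study: the constant mixing ratio [CPO]/[MALO] and the preliminary single-oxon IC50s. The stated ratio and the stated IC50s are mutually inconsistent (1/13.6 = 0.074, not 0.007); both are recorded verbatim without reconciliation and the ratio is what defines the tested mixture composition."
}
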