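op,worm_type,ic50_uM,ic50_se_uM,censored_above_uM
ACE,regenerating,,,316
CPF,regenerating,0.27,0.041,
DDVP,regenerating,0.0050,0.0010,
DZN,regenerating,0.056,0.008,
MAL,regenerating,4.9,2.0,
PFS,regenerating,0.057,0.016,
PT,regenerating,0.21,0.038,
ACE,adult,,,316
CPF,adult,0.18,0.043,
DDVP,adult,0.095,0.012,
DZN,adult,0.16,0.06,
MAL,adult,4.7,1.1,
PFS,adult,0.044,0.012,
PT,adult,0.16,0.02,
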