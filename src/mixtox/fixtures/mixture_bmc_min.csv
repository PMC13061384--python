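mixture,worm_type,experimental_bmc_min_uM,predicted_bmc_min_uM,log10_ratio
CPF.ACE,adult,0.92,1.69,0.27
CPF.DDVP,adult,0.54,0.09,-0.79
CPF.DZN,adult,0.07,0.19,0.43
CPF.MAL,adult,1.00,1.69,0.23
CPF.PFS,adult,0.07,0.25,0.54
CPF.PT,adult,0.71,1.69,0.37
DDVP.ACE,adult,1.44,0.09,-1.20
DDVP.DZN,adult,0.47,0.06,-0.87
DDVP.MAL,adult,0.32,0.09,-0.54
DDVP.PFS,adult,1.37,0.07,-1.29
DDVP.PT,adult,0.46,0.09,-0.70
DZN.ACE,adult,0.09,0.22,0.37
DZN.MAL,adult,0.08,0.22,0.44
DZN.PFS,adult,0.07,0.12,0.24
DZN.PT,adult,0.07,0.22,0.48
MAL.ACE,adult,2.72,13.50,0.70
MAL.PFS,adult,0.07,0.29,0.62
MAL.PT,adult,0.91,3.63,0.60
PFS.ACE,adult,0.08,0.29,0.56
PFS.PT,adult,0.08,0.29,0.59
PT.ACE,adult,7.91,4.96,-0.20
CPF.ACE,regenerating,2.15,1.70,-0.10
CPF.DDVP,regenerating,1.00,0.09,-1.03
CPF.DZN,regenerating,0.10,1.44,1.16
CPF.MAL,regenerating,0.68,1.70,0.40
CPF.PFS,regenerating,0.24,1.24,0.72
CPF.PT,regenerating,0.92,1.70,0.27
DDVP.ACE,regenerating,1.59,0.10,-1.20
DDVP.DZN,regenerating,0.95,0.10,-0.98
DDVP.MAL,regenerating,0.74,0.10,-0.87
DDVP.PFS,regenerating,0.99,0.10,-1.01
DDVP.PT,regenerating,1.61,0.10,-1.21
DZN.ACE,regenerating,6.22,9.15,0.17
DZN.MAL,regenerating,0.09,9.15,2.00
DZN.PFS,regenerating,3.00,3.04,0.01
DZN.PT,regenerating,0.27,8.01,1.48
MAL.ACE,regenerating,1.47,45.29,1.49
MAL.PFS,regenerating,0.21,4.56,1.34
MAL.PT,regenerating,0.68,12.97,1.28
PFS.ACE,regenerating,0.23,4.56,1.31
PFS.PT,regenerating,0.79,4.56,0.76
PT.ACE,regenerating,,,
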