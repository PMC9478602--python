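patient_id,d_fact_cgy,d_theory_cgy,pct_diff_printed
P1,213.30,211.31,0.94
P2,209.53,208.52,0.48
P3,206.37,203.16,1.58
P4,208.40,205.86,1.23
P5,211.01,209.38,0.78
P6,207.71,208.41,0.34
P7,209.57,210.86,0.61
P8,205.29,204.55,0.36
P9,210.66,212.53,0.88
P10,212.18,209.03,1.51
P11,211.63,209.92,0.81
P12,210.70,211.09,0.18
P13,208.51,207.75,0.37
P14,204.44,204.83,0.19
P15,204.99,206.63,0.79
P16,209.53,207.75,0.86
P17,208.46,208.80,0.16
P18,207.51,206.73,0.38
P19,214.11,211.01,1.47
P20,212.51,208.42,1.96
P21,209.61,208.92,0.33
P22,212.90,208.59,2.07
P23,204.14,206.03,0.92
P24,211.46,211.59,0.06
P25,205.04,209.14,1.96
P26,208.94,210.67,0.82
P27,214.42,211.36,1.45
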