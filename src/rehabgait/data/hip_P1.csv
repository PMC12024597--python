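# rehabgait-cpt v1
# child=P1
# parents=B11,B12,B21,B22,B31,B32
# child_states=gait_improvement,strength_enhancement,flexibility_restoration
# completion_rule=none
B11,B12,B21,B22,B31,B32,gait_improvement,strength_enhancement,flexibility_restoration
0,0,0,0,0,0,0.6,0.25,0.15
0,0,0,0,0,1,0.18,0.35,0.47
0,0,0,0,1,0,0.56,0.23,0.21
0,0,0,0,1,1,0.2,0.57,0.23
0,0,0,1,0,0,0.72,0.14,0.14
0,0,0,1,0,1,0.22,0.46,0.32
0,0,0,1,1,0,0.57,0.25,0.18
0,0,0,1,1,1,0.22,0.62,0.16
0,0,1,0,0,0,0.6,0.25,0.15
0,0,1,0,0,1,0.14,0.59,0.27
0,0,1,0,1,0,0.48,0.39,0.13
0,0,1,0,1,1,0.25,0.45,0.3
0,0,1,1,0,0,0.64,0.21,0.15
0,0,1,1,0,1,0.21,0.64,0.15
0,0,1,1,1,0,0.37,0.32,0.31
0,0,1,1,1,1,0.15,0.75,0.1
0,1,0,0,0,0,0.82,0.12,0.06
0,1,0,0,0,1,0.27,0.65,0.08
0,1,0,0,1,0,0.55,0.23,0.22
0,1,0,0,1,1,0.24,0.58,0.18
0,1,0,1,0,0,0.33,0.33,0.34
0,1,0,1,0,1,0.27,0.23,0.5
0,1,0,1,1,0,0.31,0.34,0.35
0,1,0,1,1,1,0.48,0.5,0.02
0,1,1,0,0,0,0.37,0.26,0.37
0,1,1,0,0,1,0.11,0.14,0.75
0,1,1,0,1,0,0.41,0.27,0.32
0,1,1,0,1,1,0.05,0.5,0.45
0,1,1,1,0,0,0.27,0.36,0.37
0,1,1,1,0,1,0.05,0.82,0.13
0,1,1,1,1,0,0.41,0.41,0.18
0,1,1,1,1,1,0.25,0.69,0.06
1,0,0,0,0,0,0.26,0.35,0.39
1,0,0,0,0,1,0.41,0.27,0.32
1,0,0,0,1,0,0.19,0.53,0.28
1,0,0,0,1,1,0.4,0.4,0.2
1,0,0,1,0,0,0.44,0.28,0.28
1,0,0,1,0,1,0.3,0.43,0.27
1,0,0,1,1,0,0.29,0.3,0.41
1,0,0,1,1,1,0.1,0.63,0.27
1,0,1,0,0,0,0.49,0.1,0.41
1,0,1,0,0,1,0.25,0.45,0.3
1,0,1,0,1,0,0.34,0.28,0.38
1,0,1,0,1,1,0.35,0.35,0.3
1,0,1,1,0,0,0.24,0.38,0.38
1,0,1,1,0,1,0.12,0.45,0.43
1,0,1,1,1,0,0.3,0.68,0.02
1,0,1,1,1,1,0.2,0.25,0.55
1,1,0,0,0,0,0.29,0.36,0.35
1,1,0,0,0,1,0.41,0.39,0.2
1,1,0,0,1,0,0.3,0.25,0.45
1,1,0,0,1,1,0.09,0.5,0.41
1,1,0,1,0,0,0.37,0.5,0.13
1,1,0,1,0,1,0.3,0.22,0.48
1,1,0,1,1,0,0.72,0.14,0.14
1,1,0,1,1,1,0.18,0.27,0.55
1,1,1,0,0,0,0.27,0.37,0.36
1,1,1,0,0,1,0.06,0.81,0.13
1,1,1,0,1,0,0.4,0.4,0.2
1,1,1,0,1,1,0.25,0.69,0.06
1,1,1,1,0,0,0.56,0.24,0.2
1,1,1,1,0,1,0.24,0.57,0.19
1,1,1,1,1,0,0.64,0.21,0.15
1,1,1,1,1,1,0.48,0.5,0.02
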