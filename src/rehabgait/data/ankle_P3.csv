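# rehabgait-cpt v1
# child=P3
# parents=B61,B62,B71,B72,B81,B82
# child_states=balance_improvement,motor_ability_enhancement,physical_fitness_improvement
# completion_rule=none
B61,B62,B71,B72,B81,B82,balance_improvement,motor_ability_enhancement,physical_fitness_improvement
0,0,0,0,0,0,0.17,0.46,0.37
0,0,0,0,0,1,0.53,0.27,0.2
0,0,0,0,1,0,0.27,0.3,0.43
0,0,0,0,1,1,0.35,0.22,0.43
0,0,0,1,0,0,0.2,0.69,0.11
0,0,0,1,0,1,0.2,0.31,0.49
0,0,0,1,1,0,0.22,0.38,0.4
0,0,0,1,1,1,0.58,0.3,0.12
0,0,1,0,0,0,0.31,0.29,0.4
0,0,1,0,0,1,0.49,0.31,0.2
0,0,1,0,1,0,0.2,0.4,0.4
0,0,1,0,1,1,0.14,0.46,0.4
0,0,1,1,0,0,0.29,0.15,0.56
0,0,1,1,0,1,0.11,0.69,0.2
0,0,1,1,1,0,0.48,0.04,0.48
0,0,1,1,1,1,0.33,0.37,0.3
0,1,0,0,0,0,0.05,0.55,0.4
0,1,0,0,0,1,0.85,0.14,0.01
0,1,0,0,1,0,0.1,0.3,0.6
0,1,0,0,1,1,0.3,0.35,0.35
0,1,0,1,0,0,0.09,0.51,0.4
0,1,0,1,0,1,0.71,0.19,0.1
0,1,0,1,1,0,0.2,0.3,0.5
0,1,0,1,1,1,0.33,0.27,0.4
0,1,1,0,0,0,0.66,0.24,0.1
0,1,1,0,0,1,0.2,0.3,0.5
0,1,1,0,1,0,0.24,0.36,0.4
0,1,1,0,1,1,0.56,0.34,0.1
0,1,1,1,0,0,0.28,0.36,0.36
0,1,1,1,0,1,0.05,0.85,0.1
0,1,1,1,1,0,0.44,0.1,0.46
0,1,1,1,1,1,0.31,0.38,0.31
1,0,0,0,0,0,0.4,0.45,0.15
1,0,0,0,0,1,0.3,0.2,0.5
1,0,0,0,1,0,0.15,0.4,0.45
1,0,0,0,1,1,0.29,0.7,0.01
1,0,0,1,0,0,0.47,0.33,0.2
1,0,0,1,0,1,0.2,0.4,0.4
1,0,0,1,1,0,0.16,0.44,0.4
1,0,0,1,1,1,0.64,0.26,0.1
1,0,1,0,0,0,0.2,0.3,0.5
1,0,1,0,0,1,0.41,0.27,0.32
1,0,1,0,1,0,0.09,0.73,0.18
1,0,1,0,1,1,0.5,0.48,0.02
1,0,1,1,0,0,0.2,0.32,0.48
1,0,1,1,0,1,0.1,0.73,0.17
1,0,1,1,1,0,0.48,0.11,0.41
1,0,1,1,1,1,0.41,0.5,0.09
1,1,0,0,0,0,0.15,0.3,0.55
1,1,0,0,0,1,0.25,0.38,0.37
1,1,0,0,1,0,0.55,0.32,0.13
1,1,0,0,1,1,0.11,0.49,0.4
1,1,0,1,0,0,0.2,0.3,0.5
1,1,0,1,0,1,0.08,0.52,0.4
1,1,0,1,1,0,0.72,0.18,0.1
1,1,0,1,1,1,0.2,0.3,0.5
1,1,1,0,0,0,0.4,0.3,0.3
1,1,1,0,0,1,0.19,0.43,0.38
1,1,1,0,1,0,0.22,0.58,0.2
1,1,1,0,1,1,0.37,0.15,0.48
1,1,1,1,0,0,0.27,0.2,0.53
1,1,1,1,0,1,0.32,0.3,0.38
1,1,1,1,1,0,0.32,0.2,0.48
1,1,1,1,1,1,0.41,0.25,0.34
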