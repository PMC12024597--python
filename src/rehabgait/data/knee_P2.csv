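# rehabgait-cpt v1
# child=P2
# parents=B41,B51,B52
# child_states=coordination_enhancement,strength_increase,flexibility_improvement
# completion_rule=none
B41,B51,B52,coordination_enhancement,strength_increase,flexibility_improvement
0,0,0,0.51,0.26,0.23
0,0,1,0.27,0.55,0.18
0,1,0,0.47,0.35,0.18
0,1,1,0.25,0.57,0.18
1,0,0,0.31,0.34,0.35
1,0,1,0.38,0.28,0.34
1,1,0,0.41,0.33,0.26
1,1,1,0.29,0.37,0.34
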