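# rehabgait-calibration v1
# units=mm
# note=CAD-verified pose/length triples for the 3-branch PRPR actuator; the row-1 branch-3 cell is not reconcilable with the branch-3 length model and is excluded by default calibration
Px_mm,Py_mm,Pz_mm,L1_mm,L2_mm,L3_mm
300,400,-1000,1187.26,1000.80,1028.39
200,350,-900,1049.57,910.82,904.49
-400,450,-950,951.89,1204.20,950.05
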