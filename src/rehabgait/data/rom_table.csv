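# rehabgait-rom v1
# units=degrees
# note=hip horizontal physiological internal-rotation limit transcribed as 70 (source prints the pair as 0-90/070; read as external 0-90, internal 0-70)
joint,plane,direction,phys_min_deg,phys_max_deg,gait_min_deg,gait_max_deg,applicable
hip,sagittal,flexion,0,140,0,40,yes
hip,sagittal,extension,0,15,0,5,yes
hip,coronal,abduction,0,30,0,5,yes
hip,coronal,adduction,0,25,0,3,yes
hip,horizontal,external_rotation,0,90,0,7,yes
hip,horizontal,internal_rotation,0,70,0,3,yes
knee,sagittal,flexion,0,140,0,67,yes
knee,sagittal,extension,0,0,0,0,yes
knee,coronal,abduction,,,,,no
knee,coronal,adduction,,,,,no
knee,horizontal,external_rotation,0,45,0,8,yes
knee,horizontal,internal_rotation,0,30,0,8,yes
ankle,sagittal,flexion,0,30,0,7,yes
ankle,sagittal,extension,0,45,0,10,yes
ankle,coronal,abduction,0,15,0,3,yes
ankle,coronal,adduction,0,20,0,3,yes
ankle,horizontal,external_rotation,0,15,0,3,yes
ankle,horizontal,internal_rotation,0,15,0,3,yes
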