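label,role,x_mm,y_mm,z_mm
FC3,source,-60.182,22.716,55.544
C3,source,-65.358,-11.632,64.358
CP3,source,-63.556,-47.009,65.624
FC5,detector,-77.215,18.643,24.460
C5,detector,-80.280,-13.760,29.160
CP5,detector,-79.592,-46.551,30.949
FC1,detector,-34.062,26.011,79.987
C1,detector,-36.158,-9.984,89.752
CP1,detector,-35.513,-47.292,91.315
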