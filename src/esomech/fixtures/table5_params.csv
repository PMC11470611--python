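direction,c_kPa,k1_kPa,k2,theta_rad
axial,9.0966,9.3158,1.8472,1.0002
circumferential,5.0863,1.1122,1.7420,1.5884
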