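sample_id,volume_A_ml_per_g,volume_B_ml_per_g,quality_class
G1,3.2,2.5,good
G2,3.5,2.7,good
G3,3.1,1.7,medium
G4,2.6,1.3,medium
G5,2.7,1.5,medium
G6,2.9,1.7,medium
G7,2.8,1.3,medium
G8,2.8,2.3,good
G9,2.9,2.0,good
G10,3.0,2.9,good
G11,3.0,2.2,good
G12,2.9,2.5,good
G13,2.6,1.2,medium
G14,2.9,2.0,good
G15,3.4,2.6,good
G16,3.2,2.3,good
G17,2.9,2.5,good
G18,3.0,2.6,good
G19,3.2,2.6,good
G20,3.2,2.6,good
G21,3.1,2.2,good
G22,3.1,2.5,good
G23,3.1,2.6,good
G24,3.1,2.9,good
G25,2.8,1.2,medium
G26,3.4,3.0,good
G27,3.1,2.8,good
G28,2.2,1.2,poor
G29,2.0,1.1,poor
G30,2.1,1.2,poor
G31,2.6,1.3,medium
G32,2.4,1.4,medium
G33,2.7,1.4,medium
G34,2.4,1.2,medium
G35,2.9,1.4,medium
G36,2.4,1.3,medium
G37,2.3,1.2,medium
G38,2.2,1.1,poor
G39,2.0,1.1,poor
G40,1.6,1.1,poor
G41,2.0,1.1,poor
G42,2.8,1.6,medium
G43,2.1,1.1,poor
G44,3.0,2.6,good
G45,2.9,2.2,good
G46,2.8,2.3,good
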