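test_id,err_axial_holzapfel,err_circ_holzapfel,err_axial_linear,err_circ_linear,err_axial_raw,err_circ_raw,corr_axial_holzapfel,corr_circ_holzapfel,corr_axial_linear,corr_circ_linear,corr_axial_raw,corr_circ_raw
T1,0.0789,0.0889,0.1181,0.1427,0.1294,0.1084,0.9999,0.9999,0.9997,0.9997,0.9998,0.9998
T2,0.0977,0.0698,0.0690,0.0536,0.0990,0.0760,1.0000,0.9999,0.9998,0.9998,0.9997,0.9998
T3,0.1430,0.1566,0.2819,0.2801,0.1921,0.1750,0.9995,0.9995,0.9987,0.9991,0.9995,0.9991
T4,0.1223,0.1148,0.1760,0.1259,0.1711,0.1275,0.9998,0.9999,0.9995,0.9996,0.9997,0.9997
T5,0.1404,0.1283,0.2100,0.3181,0.1725,0.1384,0.9999,0.9997,0.9995,0.9993,0.9997,0.9997
T6,0.1387,0.1203,0.0699,0.1531,0.1236,0.1418,1.0000,1.0000,0.9994,0.9999,0.9999,0.9999
T7,0.1245,0.1004,0.2078,0.3059,0.1588,0.1135,0.9998,0.9998,0.9996,0.9992,0.9998,0.9998
T8,0.1384,0.0738,0.0806,0.1088,0.1271,0.0868,1.0000,0.9999,0.9999,0.9998,0.9999,0.9999
T9,0.1098,0.0710,0.1851,0.1551,0.1460,0.0975,0.9999,0.9999,0.9996,0.9998,0.9998,0.9998
T10,0.0871,0.1091,0.0570,0.0524,0.0883,0.1037,0.9999,1.0000,0.9999,0.9991,0.9998,1.0000
T11,0.0933,0.1165,0.0787,0.0919,0.1064,0.1229,0.9999,0.9999,0.9997,0.9998,0.9997,0.9998
T12,0.0784,0.0914,0.0505,0.0435,0.0784,0.0840,0.9997,0.9999,0.9994,0.9997,0.9992,0.9998
T13,0.0753,0.0977,0.0546,0.2198,0.0837,0.1130,0.9998,0.9999,0.9997,0.9997,0.9996,0.9999
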