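a_test3_axial,a_test3_circ,a_test10_axial,a_test10_circ,b_test7_axial,b_test7_circ,b_test14_axial,b_test14_circ
0.9449,0.9987,0.9997,0.9997,0.9987,0.9619,0.9998,0.9996
0.8496,0.9328,0.9997,0.9998,0.9747,0.8413,0.9997,0.9995
0.9689,0.9835,0.9988,0.9992,0.9993,0.9929,0.9993,0.9992
0.9927,0.9993,0.9993,0.9996,0.9980,0.8966,0.9994,0.9996
0.7466,0.9843,0.9995,0.9997,0.9997,0.9994,0.9996,0.9996
0.9833,0.9996,0.9966,0.9999,0.8019,0.9532,0.9914,0.9999
0.6658,0.9995,0.9996,0.9997,0.7610,0.9359,0.9996,0.9998
0.9908,0.9998,0.9940,0.9998,0.9997,0.9952,0.9787,0.9998
0.7247,0.5424,0.9996,0.9998,0.9219,0.5283,0.9997,0.9998
0.8153,0.8014,0.9995,0.9996,0.9791,0.7472,0.9993,0.9619
0.7739,0.7790,0.9994,0.9996,0.9578,0.6868,0.9997,0.9993
0.7073,0.9997,0.9996,0.9999,0.8000,0.9942,0.9990,0.9834
0.8407,0.9699,0.9997,0.9998,0.9766,0.7680,0.9997,0.9999
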