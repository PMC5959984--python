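gtv_diameter_cm,margin_mm,beams,dmax_pct,dmean_pct,rtog_ci,paddick_gi
0.5,0,coplanar,101,90,2.0,14.8
0.5,0,noncoplanar,103,90,1.5,14.6
0.5,1,coplanar,123,98,2.5,9.7
0.5,1,noncoplanar,128,98,1.2,9.2
0.5,2,coplanar,135,99,1.2,7.9
0.5,2,noncoplanar,133,100,1.1,6.1
1.0,0,coplanar,126,97,1.1,6.9
1.0,0,noncoplanar,111,91,1.1,7.2
1.0,1,coplanar,127,103,1.2,5.7
1.0,1,noncoplanar,140,104,1.1,4.7
1.0,2,coplanar,118,99,1.1,4.6
1.0,2,noncoplanar,125,98,1.0,4.3
1.5,0,coplanar,127,101,1.1,4.5
1.5,0,noncoplanar,118,96,1.0,4.3
1.5,1,coplanar,121,103,1.1,4.0
1.5,1,noncoplanar,135,107,1.0,3.6
1.5,2,coplanar,118,100,1.0,4.0
1.5,2,noncoplanar,145,106,1.0,3.2
2.0,0,coplanar,116,100,1.0,3.9
2.0,0,noncoplanar,112,96,1.0,3.4
2.0,1,coplanar,130,109,1.1,3.7
2.0,1,noncoplanar,132,108,1.0,3.2
2.0,2,coplanar,120,101,1.0,3.6
2.0,2,noncoplanar,130,105,1.0,3.0
2.5,0,coplanar,122,103,1.0,3.7
2.5,0,noncoplanar,106,94,1.0,2.6
2.5,1,coplanar,124,108,1.1,3.5
2.5,1,noncoplanar,125,104,1.0,2.9
2.5,2,coplanar,124,104,1.0,3.4
2.5,2,noncoplanar,131,108,1.0,2.8
3.0,0,coplanar,126,102,1.0,3.5
3.0,0,noncoplanar,113,97,1.0,2.8
3.0,1,coplanar,126,108,1.1,3.3
3.0,1,noncoplanar,124,106,1.0,2.7
3.0,2,coplanar,126,106,1.0,3.3
3.0,2,noncoplanar,128,106,1.0,2.7
3.5,0,coplanar,131,102,1.0,3.3
3.5,0,noncoplanar,109,96,1.0,2.7
3.5,1,coplanar,124,107,1.1,3.2
3.5,1,noncoplanar,122,105,1.0,2.6
3.5,2,coplanar,128,107,1.0,3.2
3.5,2,noncoplanar,127,107,1.0,2.6
4.0,0,coplanar,135,102,1.0,3.1
4.0,0,noncoplanar,112,97,1.0,2.6
4.0,1,coplanar,121,104,1.1,3.0
4.0,1,noncoplanar,126,105,1.0,2.5
4.0,2,coplanar,134,107,1.0,3.1
4.0,2,noncoplanar,139,113,1.0,2.6
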