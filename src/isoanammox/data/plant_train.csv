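reactor,nh4_mM,no2_mM,no3_mM,d15_nh4,d15_no2,d18_no2,d15_no3,d18_no3
Influent,44.5,0,0,-10.4,n.d.,n.d.,n.d.,n.d.
DN,40.7,0.2,0,-8.4,-27.3,4.7,n.d.,n.d.
BD,32.8,7.7,0,0.6,-38.8,4.3,n.d.,n.d.
NT,18.7,21.2,0,19.2,-28.2,4.5,n.d.,n.d.
ANX,1.9,0.4,2.5,50.2,-21.6,3.3,9.3,2.7
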