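sample_id,set_id,group,age,gender,diagnosis,full_mouth_mean_pd_mm,full_mouth_bop_pct
H1,set1,healthy,53,M,H,1.8,0.0
H2,set1,healthy,43,M,H,1.8,2.1
H3,set1,healthy,26,F,H,1.8,3.6
H4,set1,healthy,37,F,H,1.8,3.5
H5,set1,healthy,31,M,H,1.8,2.6
P1,set1,periodontitis,45,F,CP,2.8,29.6
P2,set1,periodontitis,70,F,CP,2.7,5.6
P3,set1,periodontitis,41,M,AgP,3.6,51.8
H6,set2,healthy,27,M,H,2.0,1.8
H7,set2,healthy,27,M,H,1.9,3.0
H8,set2,healthy,27,F,H,2.2,3.6
H9,set2,healthy,30,F,H,2.2,3.0
H10,set2,healthy,28,M,H,2.3,2.4
H11,set2,healthy,28,F,H,1.9,3.6
P4,set2,periodontitis,67,F,CP,2.5,14.2
P5,set2,periodontitis,34,F,AgP,3.1,47.7
P6,set2,periodontitis,73,M,CP,4.4,94.4
P7,set2,periodontitis,82,F,CP,2.3,13.0
P8,set2,periodontitis,68,F,CP,3.1,55.6
P9,set2,periodontitis,68,M,CP,2.3,16.7
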