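segment_id,segment_name,mean_pct,sd_pct
1,Basal anterior,35.6,5.6
2,Basal anteroseptal,28.0,5.7
3,Basal inferoseptal,28.0,6.4
4,Basal inferior,36.4,6.1
5,Basal inferolateral,33.1,5.3
6,Basal anterolateral,35.9,5.1
7,Mid-anterior,38.1,8.4
8,Mid-anteroseptal,34.7,9.7
9,Mid-inferoseptal,32.8,11.4
10,Mid-inferior,48.4,12.4
11,Mid-inferolateral,36.5,7.9
12,Mid-anterolateral,38.3,8.3
13,Apical anterior,29.9,8.9
14,Apical septal,28.8,11.2
15,Apical inferior,30.5,11.7
16,Apical lateral,32.6,10.1
17,Apex,21.0,8.6
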