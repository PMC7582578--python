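hour,children,heat_vulnerable_area,farming_area,greenhouse,road,construction_site,shipyard
3,0,1.0,0,0,0.3,1.2,0
6,0,0,0,0,0.5,1.0,0
9,2.9,0.7,0.1,2.3,1.2,1.3,1.7
12,2.5,1.7,0.5,4.0,1.4,1.6,2.2
15,1.2,0.9,1.1,4.0,1.3,1.2,1.0
18,-0.9,0.3,0.6,2.1,0.9,0.7,0
21,0,5.0,0,1.0,0.5,1.4,0
24,0,2.5,0,0.5,0.3,1.2,0
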