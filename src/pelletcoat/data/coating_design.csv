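run_id,polymer,concentration_pct,ratio,coated_surface_pct
1,Kollidon VA64,2.5,1:1,26.3
2,Kollidon VA64,2.5,2:1,65.4
3,Kollidon VA64,1.0,1:1,26.8
4,Kollidon VA64,5.0,3:1,82.9
5,Kollicoat Protect,2.5,2:1,86.9
6,Kollicoat Protect,2.5,1:1,30.3
7,Kollidon VA64,5.0,1:1,20.0
8,Kollicoat Protect,5.0,1:1,26.1
9,Kollidon VA64,2.5,2:1,63.1
10,Kollicoat Protect,5.0,2:1,55.7
11,Kollicoat Protect,2.5,2:1,85.2
12,Kollicoat Protect,1.0,2:1,88.2
13,Kollidon VA64,1.0,3:1,93.3
14,Kollidon VA64,5.0,2:1,51.2
15,Kollicoat Protect,1.0,3:1,99.1
16,Kollicoat Protect,2.5,3:1,90.1
17,Kollidon VA64,1.0,2:1,90.7
18,Kollicoat Protect,1.0,1:1,27.9
19,Kollicoat Protect,5.0,3:1,91.0
20,Kollidon VA64,2.5,3:1,74.7
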