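municipality,department,weight
05001,05,2533424
05088,05,495483
05266,05,242197
05360,05,276744
08001,08,1206319
08758,08,603999
11001,11,7412566
13001,13,973045
13430,13,123906
15001,15,172548
17001,17,434403
19001,19,318059
23001,23,490840
25307,25,106818
25754,25,645205
41001,41,357392
47001,47,499391
50001,50,531275
52001,52,392589
54001,54,711715
66001,66,467269
66170,66,202413
68001,68,581130
68276,68,297230
70001,70,286716
73001,73,541101
76001,76,2227642
76109,76,311827
76520,76,349294
81001,81,96814
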