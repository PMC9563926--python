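mz,formula,name,prior_direction,prior_significant,provenance
63.9023,,,,,synthetic
68.4827,,,,,synthetic
70.8624,,,,,synthetic
72.863,,,,,synthetic
75.1106,,,,,synthetic
79.8212,,,,,synthetic
81.0328,C5H5O,,increased,false,attributed
84.163,,,,,synthetic
88.1905,,,,,synthetic
91.2146,,,,,synthetic
94.7776,,,,,synthetic
95.0494,C6H7O,,increased,false,attributed
101.0598,C5H9O2,,increased,false,attributed
109.695,,,,,synthetic
114.704,,,,,synthetic
116.8394,,,,,synthetic
120.7777,,,,,synthetic
125.0958,C8H13O,2-butylfuran,increased,true,attributed
128.0701,C6H10NO2,,increased,true,attributed
145.961,,,,,synthetic
152.0699,C8H10NO2,,increased,false,attributed
155.4807,,,,,synthetic
159.9133,,,,,synthetic
169.0867,C9H13O3,,increased,false,attributed
173.9983,,,,,synthetic
175.1117,C12H15O,,increased,true,attributed
183.0353,,,,,synthetic
184.6223,,,,,synthetic
185.5218,,,,,synthetic
191.2527,,,,,synthetic
191.5148,,,,,synthetic
194.3487,,,,,synthetic
195.1379,C12H19O2,4-(hexyloxy)phenol,increased,true,attributed
204.8693,,,,,synthetic
205.155,,,,,synthetic
212.2303,,,,,synthetic
228.5433,,,,,synthetic
229.0254,,,,,synthetic
229.6792,,,,,synthetic
236.6008,,,,,synthetic
251.3287,,,,,synthetic
255.7267,,,,,synthetic
257.7811,,,,,synthetic
267.3061,,,,,synthetic
268.1949,,,,,synthetic
271.9118,,,,,synthetic
275.3073,,,,,synthetic
276.6209,,,,,synthetic
295.1388,,,,,synthetic
295.2895,,,,,synthetic
297.0979,,,,,synthetic
298.1092,,,,,synthetic
304.4677,,,,,synthetic
305.4678,,,,,synthetic
323.0413,,,,,synthetic
324.5806,,,,,synthetic
329.2443,,,,,synthetic
330.2316,,,,,synthetic
338.4866,,,,,synthetic
341.739,,,,,synthetic
341.804,,,,,synthetic
342.1459,,,,,synthetic
347.3426,,,,,synthetic
349.8309,,,,,synthetic
349.9205,,,,,synthetic
351.281,,,,,synthetic
352.0468,,,,,synthetic
356.0528,,,,,synthetic
359.3963,,,,,synthetic
359.9087,,,,,synthetic
373.0877,,,,,synthetic
395.0857,,,,,synthetic
396.6722,,,,,synthetic
404.7383,,,,,synthetic
410.0723,,,,,synthetic
410.9673,,,,,synthetic
414.5609,,,,,synthetic
419.2904,,,,,synthetic
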