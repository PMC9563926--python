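mz,formula,name,prior_direction,prior_significant
81.0328,C5H5O,,increased,false
95.0494,C6H7O,,increased,false
101.0598,C5H9O2,,increased,false
125.0958,C8H13O,2-butylfuran,increased,true
128.0701,C6H10NO2,,increased,true
152.0699,C8H10NO2,,increased,false
169.0867,C9H13O3,,increased,false
175.1117,C12H15O,,increased,true
195.1379,C12H19O2,4-(hexyloxy)phenol,increased,true
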