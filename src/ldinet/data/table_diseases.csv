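name,train,val,test
Black Blight Fungus,551,140,99
Black Measles Fungus,738,184,133
Black Rot Fungus,675,168,120
Black Spot,287,76,52
Cedar Rust,146,36,26
CZTD,286,72,51
Early Blight,1126,280,201
Greening June,2903,724,531
Late Blight,1654,416,296
Leaf Blight,623,152,109
Leaf Mold,529,132,94
Leaf Spot,564,142,100
Powdery Mildew,1205,306,214
Puccinia Polysora,670,168,120
Scab,1831,460,326
Septoria Leaf Spot Fungus,980,248,175
Spider Mite Damage,649,164,116
Target Spot Bacteria,53,12,9
YLCV Virus,3107,780,555
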