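name,train,val,test
Apple,1382,348,247
Cherry,658,166,115
Citrus,3194,800,583
Corn,1824,454,325
Grape,2202,548,394
Peach,1500,378,268
Pepper,1353,336,241
Potato,1130,280,202
Pumpkin,1025,260,184
Soybean,1142,288,204
Strawberry,817,200,144
Tomato,7932,1996,1417
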