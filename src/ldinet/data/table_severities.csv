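name,train,val,test
General,7600,1893,1356
Serious,10977,2767,1971
Healthy,5582,1394,997
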