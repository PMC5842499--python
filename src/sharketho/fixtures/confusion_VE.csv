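,swim,headshake,rest,chafe,burst
swim,6995,2,0,3,0
headshake,4,17,0,1,1
rest,4,0,84,0,0
chafe,2,0,0,51,1
burst,2,1,0,0,7
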