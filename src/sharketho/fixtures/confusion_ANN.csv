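,swim,headshake,rest,chafe,burst
swim,6995,2,1,2,0
headshake,6,11,0,0,6
rest,7,0,81,0,0
chafe,6,3,0,44,1
burst,0,2,0,0,8
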