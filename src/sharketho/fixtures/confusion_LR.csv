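,swim,headshake,rest,chafe,burst
swim,6984,6,2,8,0
headshake,4,16,0,1,2
rest,15,0,73,0,0
chafe,3,3,0,48,0
burst,0,8,0,0,2
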