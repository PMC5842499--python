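,swim,headshake,rest,chafe,burst
swim,6968,24,0,8,0
headshake,1,18,0,1,3
rest,3,0,85,0,0
chafe,2,3,0,48,1
burst,0,3,0,0,7
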