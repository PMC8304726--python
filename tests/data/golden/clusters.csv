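subject_id,cluster
s001,0
s002,0
s003,0
s004,0
s005,0
s006,0
s007,1
s008,1
s009,1
s010,1
s011,1
s012,1
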