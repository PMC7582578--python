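subject,stage,reference_bpm,device_bpm
1,rest,85,85
1,stage1,109,108
1,stage2,113,114
1,stage3,119,119
1,stage4,126,125
1,stage5,140,140
1,stage6,153,152
1,stage7,165,165
1,stage8,176,176
2,rest,93,93
2,stage1,111,111
2,stage2,115,114
2,stage3,119,120
2,stage4,129,130
2,stage5,140,141
2,stage6,157,158
2,stage7,165,165
2,stage8,179,179
3,rest,83,83
3,stage1,112,113
3,stage2,116,116
3,stage3,122,122
3,stage4,131,132
3,stage5,143,143
3,stage6,156,156
3,stage7,168,168
3,stage8,180,180
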