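# plasmid<TAB>stock concentration ng/uL (local miniprep yields)
pNI1	170
pNI2	225
pNI3	125
pNI4	215
pNI5	130
pNI6	190
pNI7	140
pNI8	145
pNI9	130
pNI10	135
pHD1	235
pHD2	170
pHD3	190
pHD4	190
pHD5	220
pHD6	135
pHD7	250
pHD8	190
pHD9	135
pHD10	200
pNN1	100
pNN2	175
pNN3	250
pNN4	215
pNN5	115
pNN6	175
pNN7	185
pNN8	170
pNN9	180
pNN10	210
pNG1	175
pNG2	235
pNG3	195
pNG4	135
pNG5	125
pNG6	140
pNG7	140
pNG8	235
pNG9	215
pNG10	210
pLR-NI	150
pLR-HD	230
pLR-NN	145
pLR-NG	135
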