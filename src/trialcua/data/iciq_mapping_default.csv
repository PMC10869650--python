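term,level,decrement
item_1,2,0.004
item_1,3,0.008
item_1,4,0.012
item_2,2,0.005
item_2,3,0.010
item_2,4,0.015
item_3,2,0.006
item_3,3,0.012
item_3,4,0.018
item_4,2,0.004
item_4,3,0.008
item_4,4,0.012
item_5,2,0.008
item_5,3,0.016
item_5,4,0.024
item_6,2,0.005
item_6,3,0.010
item_6,4,0.015
item_7,2,0.006
item_7,3,0.012
item_7,4,0.018
item_8,2,0.004
item_8,3,0.008
item_8,4,0.012
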