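segment,proximal_id,distal_id,mass_fraction,cm_ratio
head,1,0,0.0694,0.5
trunk,1,8,0.4346,0.4486
right_upper_arm,2,3,0.0271,0.5772
left_upper_arm,5,6,0.0271,0.5772
right_forearm,3,4,0.0162,0.4574
left_forearm,6,7,0.0162,0.4574
right_hand,4,4,0.0061,0.0
left_hand,7,7,0.0061,0.0
right_thigh,9,10,0.1416,0.4095
left_thigh,12,13,0.1416,0.4095
right_shank,10,11,0.0433,0.4459
left_shank,13,14,0.0433,0.4459
right_foot,24,22,0.0137,0.4415
left_foot,21,19,0.0137,0.4415
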