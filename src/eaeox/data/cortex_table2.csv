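mouse_id,n_hypoxic_days,n_hyperoxic_days,mean_delta_hypoxic,sd_delta_hypoxic,mean_delta_hyperoxic,sd_delta_hyperoxic,day_largest_abs_delta,peak_behavior,day_peak_behavior
M21,7,0,-7.9,3.6,,,23,8.5,23
M22,1,2,-4.1,2.3,0.5,0.9,35,2,14
M23,7,0,-10.1,2.7,,,23,2,14
M24,7,1,-9.7,5.9,-1.0,2.4,23,4,16
M27,7,0,-6.9,3.7,,,36,3.5,23
M28,4,2,-6.6,1.4,1.8,1.3,7,11.5,14
M29,9,0,-9.1,1.1,,,23,4,18
M30,5,0,-8.6,5.0,,,23,10,16
M31,9,0,-16.8,3.2,,,23,6.5,23
M32,1,6,-2.2,2.5,0.9,0.6,14,4.5,18
M33,2,3,-4.0,0.3,1.5,3.9,18,9.5,18
M34,6,0,-5.5,1.5,,,28,9,18
M35,5,2,-5.9,1.4,-0.8,5.2,28,6,32
M36,1,4,-1.9,1.5,0.6,2.4,32,5,32
M37,6,1,-3.3,1.4,1.7,3.0,8,12,19
M38,8,1,-5.1,1.7,0.8,1.9,11,0,
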