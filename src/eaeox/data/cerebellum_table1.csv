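mouse_id,n_hypoxic_days,n_hyperoxic_days,mean_delta_hypoxic,sd_delta_hypoxic,mean_delta_hyperoxic,sd_delta_hyperoxic,day_largest_abs_delta,peak_behavior,day_peak_behavior
M02,5,0,-3.8,1.4,,,29,0,
M06,1,3,-3.1,1.2,1.8,2.3,30,7,22
M07,3,3,-4.0,3.3,1.3,0.7,14,4,16
M09,0,7,,,4.0,3.4,14,6,14
M11,8,0,-12.3,8.9,,,22,4,16
M12,1,6,-3.2,1.6,3.3,2.8,17,7.5,20
M13,7,0,-11.8,3.5,,,13,11,20
M14,8,0,-9.7,3.0,,,14,8.5,16
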