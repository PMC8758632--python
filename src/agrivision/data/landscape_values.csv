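indicator_id,v_t0,v_t1
avg_field_size,1.35,1.81
total_agri_area,1781,1737
prop_intensive,93,90
semi_natural,19.8,22.2
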