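indicator_id,vision_id,desired,weight
farm_area,AS,+1,1
livestock_units,AS,+1,1
crop_diversity,AS,-1,1
livestock_diversity,AS,-1,1
feed_import,AS,+1,2
avg_field_size,AS,+1,1
total_agri_area,AS,-1,1
prop_intensive,AS,+1,1
farmer_satisfaction,AS,any,1
societal_valuation,AS,na,0
frac_over_50,AS,na,0
successor,AS,na,0
frac_owned_land,AS,na,0
econ_situation,AS,any,1
price_trend,AS,-1,2
production_trend,AS,+1,2
off_farm_work,AS,na,0
ecological_focus_area,AS,0,1
semi_natural,AS,0,1
n_intensity,AS,na,0
pesticide_use,AS,-1,1
livestock_density,AS,na,0
farm_area,SBV,0,1
livestock_units,SBV,0,1
crop_diversity,SBV,0,1
livestock_diversity,SBV,0,1
feed_import,SBV,-1,1
avg_field_size,SBV,0,1
total_agri_area,SBV,+1,2
prop_intensive,SBV,0,1
farmer_satisfaction,SBV,+1,2
societal_valuation,SBV,+1,2
frac_over_50,SBV,+1,1
successor,SBV,+1,2
frac_owned_land,SBV,+1,1
econ_situation,SBV,+1,2
price_trend,SBV,0|+1,1
production_trend,SBV,+1,1
off_farm_work,SBV,-1,1
ecological_focus_area,SBV,0,1
semi_natural,SBV,0,1
n_intensity,SBV,0,1
pesticide_use,SBV,0,1
livestock_density,SBV,0,1
farm_area,LmZ,-1,2
livestock_units,LmZ,-1,2
crop_diversity,LmZ,+1,1
livestock_diversity,LmZ,+1,1
feed_import,LmZ,-1,2
avg_field_size,LmZ,-1,1
total_agri_area,LmZ,na,0
prop_intensive,LmZ,-1,1
farmer_satisfaction,LmZ,any,1
societal_valuation,LmZ,+1,1
frac_over_50,LmZ,+1,1
successor,LmZ,+1,1
frac_owned_land,LmZ,+1,1
econ_situation,LmZ,any,1
price_trend,LmZ,+1,1
production_trend,LmZ,-1,1
off_farm_work,LmZ,-1,1
ecological_focus_area,LmZ,+1,1
semi_natural,LmZ,+1,2
n_intensity,LmZ,-1,1
pesticide_use,LmZ,-1,2
livestock_density,LmZ,-1,1
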