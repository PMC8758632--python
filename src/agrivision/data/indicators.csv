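id,name,unit,category,scale,kind
farm_area,Farm area,ha,farm_dev,farm,quantitative
livestock_units,Livestock units,LU,farm_dev,farm,quantitative
crop_diversity,Crop diversity,count,farm_dev,farm,quantitative
livestock_diversity,Livestock diversity,count,farm_dev,farm,quantitative
feed_import,Feed import,%,farm_dev,farm,quantitative
avg_field_size,Average field size,ha,landscape_dev,landscape,quantitative
total_agri_area,Total agricultural area,ha,landscape_dev,landscape,quantitative
prop_intensive,Proportion of intensively used agricultural land,%,landscape_dev,landscape,quantitative
farmer_satisfaction,Farmer satisfaction,Likert trend,social,farm,likert_trend
societal_valuation,Societal valuation,Likert trend,social,farm,likert_trend
frac_over_50,Fraction of farmers over 50 years old,%,social,landscape,one_time
successor,Successor,%,social,landscape,one_time
frac_owned_land,Fraction of owned land,%,social,farm,quantitative
econ_situation,Farm economic situation,Likert trend,economic,farm,likert_trend
price_trend,Price trend,% of t0 price,economic,farm,quantitative
production_trend,Production trend,% of t0 volume,economic,farm,quantitative
off_farm_work,Off-farm work,%,economic,farm,quantitative
ecological_focus_area,Ecological focus area,% of farm area,environmental,farm,quantitative
semi_natural,Semi-natural habitats,% of landscape area,environmental,landscape,quantitative
n_intensity,N intensity,kg N ha⁻¹,environmental,farm,quantitative
pesticide_use,Pesticide use,count,environmental,farm,quantitative
livestock_density,Livestock density,LU ha⁻¹,environmental,farm,quantitative
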