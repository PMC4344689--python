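indicator,factor,orientation,env_lo,b1,b2,b3,b4,env_hi,weight
precipitation,hazard,risk-decreasing,330.92,348.33,366.19,388.51,414.40,444.76,0.1025
evaporation,hazard,risk-increasing,1813.9,1846.4,1876.9,1927.3,1996.7,2081.8,0.0321
sand_driving_wind_days,hazard,risk-increasing,53,57,60,63,67,71,0.0699
temperature,hazard,risk-increasing,6.68,6.80,6.89,6.98,7.07,7.22,0.0338
vegetation_coverage_index,hazard,risk-decreasing,0.17,0.37,0.51,0.63,0.74,0.90,0.0527
cultivation_rate,hazard,risk-increasing,0,11,33,56,80,100,0.0655
grazing_capacity,hazard,risk-increasing,0,21,59,104,155,197,0.0523
grassland_area,exposure,risk-increasing,0,0.11,0.30,0.53,0.79,1,0.0400
farmland_area,exposure,risk-increasing,0,0.13,0.30,0.59,0.80,1,0.0540
population_density,exposure,risk-increasing,0,77,222,438,1172,2844,0.0605
economic_density,exposure,risk-increasing,0,43,110,196,340,629,0.0510
soil_properties_grassland,vulnerability,risk-increasing,0.17,0.24,0.30,0.38,0.49,0.67,0.0571
soil_properties_farmland,vulnerability,risk-increasing,0.18,0.25,0.32,0.41,0.51,0.67,0.0572
agricultural_population_ratio,vulnerability,risk-increasing,0,86,91,96,98,100,0.0448
primary_industry_gdp_ratio,vulnerability,risk-increasing,0,3,8,11,14,17,0.0401
returning_farmland_area,restorability,risk-decreasing,0,7.88,12.00,13.83,18.06,29.14,0.0576
population_output,restorability,risk-decreasing,519,4580,6090,6652,15412,19546,0.0339
number_of_students,restorability,risk-decreasing,4519,4602,4999,5745,6590,7650,0.0434
sand_control_inputs_ratio,restorability,risk-decreasing,0.68,2.18,2.77,3.19,4.25,6.64,0.0516
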