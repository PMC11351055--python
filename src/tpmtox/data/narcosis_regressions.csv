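group,phase,neg_log_c_crit,se_intercept,slope_m,se_slope,rmse,r2,n
baseline,phospholipid,1.071,0.069,0.962,0.022,0.322,0.942,115
baseline,storage_lipid,1.627,0.060,0.762,0.018,0.331,0.939,115
baseline,pooled_lipid,1.369,0.061,0.854,0.019,0.314,0.945,115
baseline,muscle_protein,1.800,0.055,1.121,0.026,0.325,0.941,115
baseline,serum_protein,0.881,0.070,1.162,0.026,0.310,0.946,115
baseline,octanol,1.127,0.078,0.900,0.024,0.367,0.925,115
baseline,PDMS,1.933,0.066,0.780,0.023,0.406,0.908,115
baseline,PA,1.403,0.059,0.954,0.021,0.307,0.947,115
baseline,POM,1.774,0.059,0.971,0.024,0.344,0.934,115
baseline,PE,2.034,0.061,0.808,0.023,0.387,0.916,115
baseline,PU,3.803,0.030,0.828,0.019,0.319,0.943,115
less_inert,phospholipid,2.153,0.111,0.737,0.032,0.292,0.880,73
less_inert,storage_lipid,3.144,0.109,0.552,0.038,0.420,0.751,73
less_inert,pooled_lipid,2.677,0.111,0.646,0.035,0.353,0.824,73
less_inert,muscle_protein,2.767,0.089,0.806,0.037,0.302,0.872,73
less_inert,serum_protein,2.013,0.109,0.857,0.035,0.275,0.894,73
less_inert,octanol,2.529,0.115,0.628,0.033,0.344,0.833,73
less_inert,PDMS,3.660,0.095,0.575,0.048,0.486,0.666,73
less_inert,PA,2.317,0.096,0.739,0.030,0.270,0.897,73
less_inert,POM,2.574,0.093,0.806,0.035,0.289,0.882,73
less_inert,PE,3.352,0.096,0.662,0.045,0.422,0.749,73
less_inert,PU,4.396,0.032,0.674,0.026,0.264,0.902,73
reactive,phospholipid,3.623,0.150,0.609,0.083,0.890,0.423,75
reactive,storage_lipid,4.098,0.113,0.439,0.061,0.899,0.412,75
reactive,pooled_lipid,3.887,0.125,0.522,0.071,0.888,0.426,75
reactive,muscle_protein,4.064,0.116,0.694,0.099,0.904,0.404,75
reactive,serum_protein,3.528,0.167,0.696,0.101,0.912,0.394,75
reactive,octanol,3.723,0.144,0.568,0.081,0.905,0.404,75
reactive,PDMS,4.374,0.107,0.412,0.062,0.923,0.380,75
reactive,PA,3.816,0.135,0.565,0.081,0.907,0.401,75
reactive,POM,3.995,0.122,0.546,0.079,0.912,0.395,75
reactive,PE,4.339,0.103,0.484,0.065,0.886,0.429,75
reactive,PU,4.396,0.032,0.674,0.026,0.907,0.401,75
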