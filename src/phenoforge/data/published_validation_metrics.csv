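algorithm,database,sensitivity,sensitivity_ci_low,sensitivity_ci_high,ppv,ppv_ci_low,ppv_ci_high,specificity,specificity_ci_low,specificity_ci_high,npv,npv_ci_low,npv_ci_high
incident_1x,CCAE,0.380,0.367,0.393,0.599,0.582,0.615,0.999,0.999,0.999,0.998,0.998,0.998
incident_1x,Clinformatics,0.369,0.358,0.380,0.603,0.589,0.617,0.999,0.999,0.999,0.998,0.997,0.998
incident_1x,MDCD,0.311,0.306,0.317,0.676,0.668,0.685,0.998,0.998,0.998,0.990,0.990,0.990
incident_1x,MDCR,0.298,0.277,0.319,0.444,0.417,0.472,1.000,1.000,1.000,0.999,0.999,0.999
incident_1x,OptumEHR,0.279,0.269,0.289,0.777,0.761,0.793,1.000,1.000,1.000,0.997,0.997,0.997
incident_2x,CCAE,0.151,0.142,0.161,0.890,0.868,0.909,1.000,1.000,1.000,0.998,0.998,0.998
incident_2x,Clinformatics,0.133,0.126,0.141,0.882,0.862,0.900,1.000,1.000,1.000,0.997,0.996,0.997
incident_2x,MDCD,0.115,0.112,0.119,0.874,0.862,0.885,1.000,1.000,1.000,0.987,0.987,0.987
incident_2x,MDCR,0.109,0.095,0.123,0.830,0.778,0.874,1.000,1.000,1.000,0.999,0.999,0.999
incident_2x,OptumEHR,0.109,0.102,0.116,0.948,0.931,0.962,1.000,1.000,1.000,0.997,0.996,0.997
prevalent_1x,CCAE,0.541,0.531,0.551,0.649,0.639,0.660,0.999,0.999,0.999,0.998,0.998,0.998
prevalent_1x,Clinformatics,0.666,0.655,0.677,0.602,0.591,0.613,0.998,0.998,0.998,0.999,0.999,0.999
prevalent_1x,MDCD,0.664,0.658,0.670,0.628,0.621,0.634,0.995,0.995,0.995,0.996,0.996,0.996
prevalent_1x,MDCR,0.442,0.422,0.462,0.355,0.338,0.373,0.999,0.999,0.999,0.999,0.999,0.999
prevalent_1x,OptumEHR,0.632,0.618,0.647,0.754,0.739,0.768,1.000,1.000,1.000,0.999,0.999,0.999
prevalent_2x,CCAE,0.296,0.285,0.307,0.874,0.860,0.887,1.000,1.000,1.000,0.997,0.997,0.998
prevalent_2x,Clinformatics,0.233,0.220,0.246,0.937,0.920,0.951,1.000,1.000,1.000,0.998,0.998,0.998
prevalent_2x,MDCD,0.219,0.203,0.236,0.732,0.699,0.764,1.000,1.000,1.000,0.999,0.999,0.999
prevalent_2x,MDCR,0.288,0.282,0.294,0.859,0.851,0.867,0.999,0.999,0.999,0.992,0.992,0.992
prevalent_2x,OptumEHR,0.231,0.222,0.239,0.912,0.900,0.923,1.000,1.000,1.000,0.996,0.996,0.996
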