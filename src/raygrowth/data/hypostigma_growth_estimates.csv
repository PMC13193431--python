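sex,model,dw0_mm,dw_inf_mm,dw_inf_sd,dw_inf_ci_low,dw_inf_ci_high,k_per_year,k_sd,t0_years,t0_sd,aic
male,vbgm2,,388.95,3.46,382.50,395.88,0.45,0.02,,,0.031
male,vbgm3,212.53,426.76,6.20,415.32,439.52,0.25,0.01,-2.77,0.12,0.157
male,gompertz,216.12,411.26,4.68,402.57,420.88,0.35,0.02,-1.26,0.04,0.087
male,logistic,217.08,401.70,3.85,394.67,409.41,0.45,0.02,-0.36,0.04,-0.042
female,vbgm2,,506.15,13.4,481.51,534.08,0.22,0.02,,,-0.001
female,vbgm3,228.18,588.96,34.0,532.78,663.92,0.13,0.02,-3.77,0.34,-0.109
female,gompertz,224.04,537.03,19.8,503.86,581.29,0.21,0.02,-0.64,0.14,0.025
female,logistic,225.80,512.22,14.6,486.48,543.97,0.29,0.02,0.82,0.21,-0.138
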