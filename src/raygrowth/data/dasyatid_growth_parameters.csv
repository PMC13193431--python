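species,size_class,region,model,sex,dw0_mm,dw_inf_mm,k_per_year,t0_years,age_max_years,n,source,excluded_flag
Dasyatis hypostigma,medium,Brazilian Meridional Margin,logistic,male,217.0,401.7,0.45,-0.36,10,201,BMM study,0
Dasyatis hypostigma,medium,Brazilian Meridional Margin,logistic,female,225.8,512.2,0.29,0.82,11,71,BMM study,0
Dasyatis hypostigma,medium,Uruguay-Argentina,logistic,male,223.5,468.2,0.3,0.3,7,22,Ruocco,0
Dasyatis hypostigma,medium,Uruguay-Argentina,logistic,female,242.1,568.9,0.2,1.5,13,29,Ruocco,0
Dasyatis pastinaca,large,Mediterranean Sea,vbgm3,pooled,162.6,1215.0,0.089,-1.615,10,256,Ismen,0
Dasyatis pastinaca,large,Mediterranean Sea,vbgm3,pooled,106.2,1044.3,0.075,-1.43,13,384,Girgin & Basusta,0
Dasyatis pastinaca,large,Mediterranean Sea,vbgm3,male,158.4,1145.4,0.041,-3.63,13,175,Girgin & Basusta,0
Dasyatis pastinaca,large,Mediterranean Sea,vbgm3,female,106.5,1270.6,0.058,-1.51,13,209,Girgin & Basusta,0
Dasyatis pastinaca,medium,Aegean Sea,vbgm3,pooled,7.4,582.8,0.06,-0.213,13,72,Yeldan & Gundogdu,1
Dasyatis marmorata,medium,Aegean Sea,vbgm3,pooled,31.8,460.9,0.36,-0.162,13,143,Yeldan & Gundogdu,1
Bathytoshia lata,large,Hawai'i,logistic,male,405.0,1166.0,0.14,4.52,25,88,Dale & Holland,0
Bathytoshia lata,large,Hawai'i,logistic,female,406.0,1441.0,0.12,7.61,28,115,Dale & Holland,0
Hypanus dipterurus,medium,Pacific Mexico,vbgm3,male,313.0,622.0,0.1,-6.8,19,148,Smith et al.,0
Hypanus dipterurus,large,Pacific Mexico,vbgm3,female,314.0,924.0,0.05,-7.61,28,191,Smith et al.,0
Dasyatis chrysonota,medium,Eastern South Africa,vbgm3,male,251.1,531.8,0.175,-3.65,5,105,Cowley,0
Dasyatis chrysonota,large,Eastern South Africa,vbgm3,female,245.9,913.4,0.07,-4.48,7,165,Cowley,0
Hypanus guttatus,medium,Ceara NE Brazil,vbgm2,male,145.0,602.2,0.219,,9,95,Gianeti et al.,0
Hypanus guttatus,large,Ceara NE Brazil,vbgm2,female,145.0,986.1,0.112,,14,101,Gianeti et al.,0
Hypanus guttatus,medium,Pernambuco NE Brazil,vbgm3,pooled,168.7,660.1,0.18,-1.64,13,203,Vieira,0
Hypanus guttatus,medium,Maranhao NE Brazil,vbgm3,pooled,267.3,602.8,0.2,-2.93,15,59,Vieira,0
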