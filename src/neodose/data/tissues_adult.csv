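tissue,freq_MHz,eps_r,sigma_S_per_m,rho_kg_m3,k_W_mK,c_J_kgK,perfusion_ml_min_kg,qmet_W_kg,source
skin,297,49.9,0.64,1109,0.37,3391,106,1.65,adult database (dry skin)
fat,297,11.7,0.077,911,0.21,2348,33,0.51,adult database
muscle,297,58.2,0.77,1090,0.49,3421,37,0.96,adult database
bone,297,13.4,0.083,1908,0.32,1313,10,0.15,adult database (cortical)
cartilage,297,46.8,0.59,1100,0.47,3568,35,0.54,adult database
brain,297,52.0,0.63,1046,0.55,3630,550,11.4,adult database (grey/white average)
csf,297,72.8,2.22,1007,0.57,4096,0,0,adult database
blood,297,65.7,1.32,1050,0.52,3617,0,0,adult database (pool itself; exchange handled separately)
heart,297,63.9,0.98,1081,0.56,3686,1026,39.5,adult database (myocardium)
lung,297,23.7,0.38,394,0.39,3886,400,0.61,adult database (inflated)
liver,297,50.8,0.65,1079,0.52,3540,860,9.9,adult database
stomach,297,64.0,1.00,1088,0.53,3690,460,0.63,adult database
connective,297,46.0,0.60,1027,0.39,2372,37,0.58,adult database (generic connective tissue)
blanket,297,1.2,0.0,150,0.04,1300,0,0,wool insulation layer (assumption)
skin,127,53.5,0.54,1109,0.37,3391,106,1.65,adult database (dry skin)
fat,127,12.4,0.068,911,0.21,2348,33,0.51,adult database
muscle,127,63.5,0.72,1090,0.49,3421,37,0.96,adult database
bone,127,14.7,0.067,1908,0.32,1313,10,0.15,adult database (cortical)
cartilage,127,53.9,0.49,1100,0.47,3568,35,0.54,adult database
brain,127,60.0,0.51,1046,0.55,3630,550,11.4,adult database (grey/white average)
csf,127,84.0,2.14,1007,0.57,4096,0,0,adult database
blood,127,73.2,1.25,1050,0.52,3617,0,0,adult database (pool itself; exchange handled separately)
heart,127,84.3,0.77,1081,0.56,3686,1026,39.5,adult database (myocardium)
lung,127,29.5,0.32,394,0.39,3886,400,0.61,adult database (inflated)
liver,127,64.2,0.51,1079,0.52,3540,860,9.9,adult database
stomach,127,74.9,0.91,1088,0.53,3690,460,0.63,adult database
connective,127,51.9,0.49,1027,0.39,2372,37,0.58,adult database (generic connective tissue)
blanket,127,1.2,0.0,150,0.04,1300,0,0,wool insulation layer (assumption)
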