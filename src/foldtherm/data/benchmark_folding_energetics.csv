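system_id,quantity,exp,exp_se,calc,calc_se,units,outlier
barnase_pH4.1,dH,118.7,4.9,110.4,3.1,kcal/mol,False
nuclease_pH7.0,dH,82.1,4.7,75.1,4.5,kcal/mol,False
nuclease_pH5.0,dH,73.1,0.1,71.0,4.5,kcal/mol,False
ci2_wt_pH3.0,dH,61.0,2.3,46.1,1.9,kcal/mol,False
ci2_i76a_pH3.0,dH,30.2,,27.7,1.7,kcal/mol,False
ci2_wt_pH6.3,dH,78.4,0.7,57.1,0.5,kcal/mol,False
apofld_F-to-I,dH,32.0,1.1,35.6,6.0,kcal/mol,False
apofld_I-to-U,dH,55.6,2.0,48.1,4.1,kcal/mol,False
apofld_F-to-U,dH,87.6,3.1,83.7,10.1,kcal/mol,False
holofld_par2,dH,101.9,0.6,,,kcal/mol,False
nuclease_pH4.1,dH,,,,,kcal/mol,True
lysozyme_wt_pH2.4,dH,,,,,kcal/mol,True
lysozyme_i3e_pH2.4,dH,,,,,kcal/mol,True
lysozyme_pseudo_pH3.0,dH,,,,,kcal/mol,True
lysozyme_pseudo_pH3.7,dH,,,,,kcal/mol,True
barnase_pH4.1,dCp,1.4,0.1,1.0,0.1,kcal/mol.K,False
nuclease_pH7.0,dCp,2.3,0.3,1.7,0.3,kcal/mol.K,False
nuclease_pH5.0,dCp,2.3,0.1,1.5,0.4,kcal/mol.K,False
ci2_wt_pH3.0,dCp,0.72,,0.4,0.03,kcal/mol.K,False
ci2_i76a_pH3.0,dCp,0.7,,0.5,0.01,kcal/mol.K,False
ci2_wt_pH6.3,dCp,0.8,0.1,0.5,0.07,kcal/mol.K,False
apofld_F-to-I,dCp,1.35,0.3,1.5,0.1,kcal/mol.K,False
apofld_I-to-U,dCp,1.55,0.3,1.0,0.0,kcal/mol.K,False
apofld_F-to-U,dCp,2.9,0.6,2.5,0.1,kcal/mol.K,False
holofld_par2,dCp,3.5,0.6,2.9,0.6,kcal/mol.K,False
nuclease_pH4.1,dCp,,,,,kcal/mol.K,True
lysozyme_wt_pH2.4,dCp,,,,,kcal/mol.K,True
lysozyme_i3e_pH2.4,dCp,,,,,kcal/mol.K,True
lysozyme_pseudo_pH3.0,dCp,,,,,kcal/mol.K,True
lysozyme_pseudo_pH3.7,dCp,,,,,kcal/mol.K,True
barnase_pH4.1,dG,7.8,0.4,7.5,1.2,kcal/mol,False
nuclease_pH7.0,dG,4.3,0.3,4.8,1.7,kcal/mol,False
nuclease_pH5.0,dG,3.5,0.1,4.4,2.8,kcal/mol,False
ci2_wt_pH3.0,dG,5.4,0.7,4.3,0.4,kcal/mol,False
ci2_i76a_pH3.0,dG,1.1,0.3,1.0,0.2,kcal/mol,False
ci2_wt_pH6.3,dG,7.2,0.4,6.9,0.6,kcal/mol,False
apofld_F-to-I,dG,1.1,1.4,1.3,1.7,kcal/mol,False
apofld_I-to-U,dG,2.9,1.3,3.0,0.9,kcal/mol,False
apofld_F-to-U,dG,4.0,2.7,4.3,2.6,kcal/mol,False
holofld_par2,dG,17.1,2.7,17.3,2.6,kcal/mol,False
nuclease_pH4.1,dG,2.9,0.3,4.8,2.2,kcal/mol,True
lysozyme_wt_pH2.4,dG,,,,,kcal/mol,True
lysozyme_i3e_pH2.4,dG,,,,,kcal/mol,True
lysozyme_pseudo_pH3.0,dG,,,,,kcal/mol,True
lysozyme_pseudo_pH3.7,dG,,,,,kcal/mol,True
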