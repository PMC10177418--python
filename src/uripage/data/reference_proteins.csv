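name,mw_kda,category,fraction,psm
Ceruloplasmin,122.13,other,1,28
Complement factor H,139.01,other,1,17
Plasminogen,90.51,other,2,29
Complement component C6,104.72,other,2,17
Complement component C7,93.46,other,2,12
Inter-alpha-trypsin inhibitor heavy chain H,103.29,other,2,11
Serotransferrin,77.01,glomerular_indicator,3,550
Coagulation factor XIII B chain,75.46,other,3,104
Kininogen,71.91,other,3,65
Afamin,69.02,other,3,34
Protein disulfide-isomerase A4,72.89,other,3,18
Albumin,69.23,glomerular_indicator,4;5;6,2756
Complement component C9,63.13,other,4,55
Hemopexin,51.64,other,5;6,308
Antithrombin-III,52.57,other,5;6,104
Pigment epithelium-derived factor,46.28,other,6;7,411
Vitamin D-binding protein,52.88,other,6;7,295
Apolipoprotein A-IV,45.34,other,6;7,471
EGF-containing fibulin-like extracellular matrix protein 1,54.60,other,7,22
Protein AMBP,38.97,tubular_indicator,8;9,933
Zinc-alpha-2-glycoprotein,34.24,other,8,62
Beta-2-glycoprotein,38.27,other,8,51
Insulin-like growth factor-binding protein 2,34.79,other,8,22
CD-5 antigen like,38.06,other,9,42
Mimecan,33.90,other,9,31
Apolipoprotein A-I,30.76,other,9;10;11,438
Corticotropin-releasing factor-binding protein,36.12,other,9,28
Complement factor D,27.02,other,10,532
Immunoglobulin kappa light chain,23.36,overload_indicator,10;11,499
Phosphatidylethanolamine-binding protein 4,25.72,other,10,130
Prostaglandin-H2 D-isomerase,21.02,other,10,87
Retinol-binding protein 4,22.99,tubular_indicator,11;12;13,777
Neutrophil gelatinase-associated lipocalin,22.57,tubular_indicator,11;12,56
Protein FAM3C,24.67,other,12,56
Tetranectin,22.52,other,12,27
Transgelin,22.60,other,12,18
Ganglioside GM2 activator,20.83,other,12,16
Metalloproteinase inhibitor 2,24.38,other,12,16
Retinoic acid receptor responder protein 2,18.61,other,13,96
Myoglobin,17.17,overload_indicator,13,82
Peptidyl-prolyl cis-trans isomerase A,18.00,other,13,52
Transthyretin,15.88,other,13,33
Cystatin C,15.79,tubular_indicator,14;15,608
Lysozyme C,16.53,overload_indicator,14,288
"Fatty acid-binding protein, adipocyte",14.71,other,14,107
Profilin-1,15.05,other,14,51
"Fatty acid-binding protein, liver",14.20,other,14,38
Hemoglobin subunit beta,15.99,overload_indicator,14,27
Beta-2-microglobulin,13.71,tubular_indicator,15,251
Cystatin M,16.50,other,15,34
Immunoglobulin free light chain dimer,46.00,overload_indicator,,
Ovalbumin,45.00,overload_indicator,,
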