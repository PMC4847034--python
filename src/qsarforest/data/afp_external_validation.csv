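chemical_name,experiment,prediction
17-alpha-Ethynylestradiol,1,1
11-beta-Ethyloxyestradiol,1,0
11-beta-Methoxyestradiol,1,1
Compound 7b,1,0
16-alpha-Fluoroestradiol (FES),1,1
Compound 8b,1,0
Compound 8c,1,1
Compound 3,1,1
Compound 1,1,0
Compound 2,1,0
Compound 7c,1,1
11-beta-Ethyl-17-alpha-ethynylestradiol,1,0
11-beta-Ethylestradiol,1,0
Compound 8a,1,0
17-alpha-Ethynyl-11-beta-Methoxyestradiol,1,0
Compound 7a,1,0
4-Nonylphenoxyacetic acid (NP1EC),1,1
4-tert-Butylphenol (BP),0,0
Igepal,0,0
"2,4'-DDT",0,0
"2,4'-DDE",0,0
Kepone,0,0
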