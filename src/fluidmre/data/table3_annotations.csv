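entity,stiffer,tumor_regime,control_regime,heterogeneous,het_redundant,front,printed_type,bracketed_type
Brain - Necrosis,False,fluid,redundant,True,True,diffuse,3,
Liver - FNH,True,transitional,solid,True,True,sharp,2,
Liver - HCA,False,solid,solid,True,True,sharp,1,
Liver - HEM,True,fluid,solid,True,False,sharp,4,2
Liver - CCA,True,fluid,solid,True,False,sharp,4,
Liver - HCC,True,fluid,transitional,True,False,sharp,4,
Brain - MEN,False,fluid,solid/transitional,True,False,sharp,1,2
Brain - GM,False,solid,solid/transitional,True,False,diffuse,3,4
Pancreas Ca,True,fluid,transitional,True,False,sharp,4,
Prostate Ca,True,fluid,transitional/fluid,True,False,redundant,4,
Colorectal Ca,True,fluid,solid/transitional,True,True,diffuse,4,
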