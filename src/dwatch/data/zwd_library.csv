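id,name,herb,class,ion_mode,mz,response_factor
hypaconitine,hypaconitine,Fuzi,diester_toxic,pos,616,20.0
benzoylhypaconitine,benzoylhypaconitine,Fuzi,monoester_active,pos,574,40.0
benzoylmesaconine,benzoylmesaconine,Fuzi,monoester_active,pos,590,200.0
benzoylaconitine,benzoylaconitine,Fuzi,monoester_active,pos,604,40.0
mesaconine,mesaconine,Fuzi,aminoalcohol,pos,486,100.0
hypaconine,hypaconine,Fuzi,aminoalcohol,pos,470,25.0
aconine,aconine,Fuzi,aminoalcohol,pos,500,25.0
songorine,songorine,Fuzi,stable_dissolution_only,pos,358,10.0
paeoniflorin,paeoniflorin,Baishao,declining_glycoside,neg,525,100.0
pentagalloylglucose,"1,2,3,4,6-pentagalloylglucose",Baishao,intermediate_biphasic,neg,939,10.0
gallic_acid,gallic acid,Baishao,hydrolysis_product_rising,neg,169,50.0
ellagic_acid,ellagic acid,Baishao,hydrolysis_product_rising,neg,301,10.0
shogaol_6,6-shogaol,Shengjiang,conversion_product,pos,277,10.0
zingerone,zingerone,Shengjiang,conversion_product,pos,195,20.0
atractylenolide_1,atractylenolide I,Baizhu,stable_dissolution_only,pos,231,10.0
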