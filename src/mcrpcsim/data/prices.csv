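drug,unit_cost,package_content,unit_kind
bicalutamide,1.61,50.0,tablet
abiraterone,28.3333,250.0,tablet
cabazitaxel,5840.0,60.0,vial
docetaxel,599.79,160.0,vial
prednisone,0.022,5.0,tablet
dexamethasone,3.24,10.0,vial
diphenhydramine,2.98,50.0,vial
famotidine,2.71,20.0,vial
goserelin,1113.0,10.8,depot
denosumab,538.45,120.0,vial
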