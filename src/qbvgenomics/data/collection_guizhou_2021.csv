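species,count,level
Culex,17201,genus
Armigeres,10962,genus
Anopheles,3750,genus
Aedes,264,genus
Cx. tritaeniorhynchus,15661,species
Ar. subalbatus,10962,species
An. sinensis,3750,species
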