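region_key,island_group,n_species
Spain,,3
Portugal,,2
France,,2
United Kingdom,,2
Ireland,,2
Azores,Azores,1
Madeira,Madeira,1
Canary Islands,Canary Islands,1
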