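original_name,revised_species,category,change_type,note
Hedera azorica,Hedera azorica,correct,same_concept,
Hedera canariensis,Hedera azorica,misidentification,plain_error,distinct extant species wrongly applied
Hedera helix,Hedera azorica,misidentification,plain_error,
Hedera helix var. azorica,Hedera azorica,soft_change,rank_change,infraspecific elevated to species
Hedera helix var. canariensis,Hedera azorica,misidentification,plain_error,
Hedera helix var. hibernica,Hedera azorica,misidentification,plain_error,
Hedera canariensis,Hedera canariensis,correct,same_concept,
Hedera helix,Hedera canariensis,misidentification,plain_error,
Hedera helix var. canariensis,Hedera canariensis,soft_change,rank_change,infraspecific elevated to species
Hedera algeriensis,Hedera helix,soft_change,synonym,legacy name subsumed
Hedera arborea,Hedera helix,soft_change,synonym,legacy name subsumed
Hedera caucasica,Hedera helix,soft_change,synonym,legacy name subsumed
Hedera colchica,Hedera helix,misidentification,plain_error,distinct extant species
Hedera helix,Hedera helix,correct,same_concept,
Hedera helix var. arborea,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera helix var. burgalensis,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera helix var. floribunda,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera helix var. helix,Hedera helix,soft_change,rank_change,autonym merged into species
Hedera helix var. minima,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera helix var. paniculata,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera helix var. pedunculata,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera helix var. poetarum,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera helix var. rhizomatifera,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera helix var. sarniensis,Hedera helix,misidentification,plain_error,
Hedera helix var. typica,Hedera helix,soft_change,rank_change,infraspecific merged into species
Hedera hibernica,Hedera helix,misidentification,plain_error,
Hedera poetarum,Hedera helix,soft_change,synonym,legacy name subsumed
Hedera taurica,Hedera helix,soft_change,synonym,legacy name subsumed
Hedera canariensis,Hedera hibernica,hard_change,nomenclatural_confusion,canariensis historically applied to SW Iberian ivies
Hedera congesta,Hedera hibernica,misidentification,plain_error,
Hedera helix,Hedera hibernica,misidentification,plain_error,systematic confusion of the two species
Hedera helix var. borealis,Hedera hibernica,misidentification,plain_error,
Hedera helix var. canariensis,Hedera hibernica,hard_change,nomenclatural_confusion,canariensis historically applied to SW Iberian ivies
Hedera helix var. digitata,Hedera hibernica,misidentification,plain_error,
Hedera helix var. helix,Hedera hibernica,misidentification,plain_error,
Hedera helix var. hibernica,Hedera hibernica,soft_change,rank_change,infraspecific elevated to species
Hedera helix var. sarniensis,Hedera hibernica,misidentification,plain_error,
Hedera helix var. sarracena,Hedera hibernica,misidentification,plain_error,
Hedera hibernica,Hedera hibernica,correct,same_concept,
Hedera canariensis,Hedera iberica,hard_change,nomenclatural_confusion,canariensis historically applied to SW Iberian ivies
Hedera helix,Hedera iberica,misidentification,plain_error,
Hedera helix var. canariensis,Hedera iberica,hard_change,nomenclatural_confusion,canariensis historically applied to SW Iberian ivies
Hedera helix var. helix,Hedera iberica,misidentification,plain_error,
Hedera helix var. rhizomatifera,Hedera iberica,misidentification,plain_error,
Hedera hibernica,Hedera iberica,misidentification,plain_error,
Hedera iberica,Hedera iberica,correct,same_concept,
Hedera maderensis var. iberica,Hedera iberica,soft_change,split_allopatric,allopatric split elevated to species
Hedera canariensis,Hedera maderensis,hard_change,nomenclatural_confusion,canariensis historically applied to Madeiran ivies
Hedera helix,Hedera maderensis,misidentification,plain_error,
Hedera helix var. canariensis,Hedera maderensis,hard_change,nomenclatural_confusion,canariensis historically applied to Madeiran ivies
Hedera helix var. helix,Hedera maderensis,misidentification,plain_error,
Hedera maderensis,Hedera maderensis,correct,same_concept,
Hedera maderensis var. maderensis,Hedera maderensis,soft_change,rank_change,autonym merged into species
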