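original_name,Hedera azorica,Hedera canariensis,Hedera helix,Hedera hibernica,Hedera iberica,Hedera maderensis
Hedera algeriensis,0,0,1,0,0,0
Hedera arborea,0,0,1,0,0,0
Hedera azorica,14,0,0,0,0,0
Hedera canariensis,12,19,0,2,6,6
Hedera caucasica,0,0,1,0,0,0
Hedera colchica,0,0,2,0,0,0
Hedera congesta,0,0,0,1,0,0
Hedera helix,3,4,475,103,15,3
Hedera helix var. arborea,0,0,1,0,0,0
Hedera helix var. azorica,1,0,0,0,0,0
Hedera helix var. borealis,0,0,0,1,0,0
Hedera helix var. burgalensis,0,0,1,0,0,0
Hedera helix var. canariensis,2,21,0,2,7,3
Hedera helix var. digitata,0,0,0,1,0,0
Hedera helix var. floribunda,0,0,2,0,0,0
Hedera helix var. helix,0,0,26,11,3,1
Hedera helix var. hibernica,2,0,0,3,0,0
Hedera helix var. minima,0,0,1,0,0,0
Hedera helix var. paniculata,0,0,1,0,0,0
Hedera helix var. pedunculata,0,0,1,0,0,0
Hedera helix var. poetarum,0,0,2,0,0,0
Hedera helix var. rhizomatifera,0,0,3,0,1,0
Hedera helix var. sarniensis,0,0,1,3,0,0
Hedera helix var. sarracena,0,0,0,1,0,0
Hedera helix var. typica,0,0,1,0,0,0
Hedera hibernica,0,0,9,24,1,0
Hedera iberica,0,0,0,0,1,0
Hedera maderensis,0,0,0,0,0,5
Hedera maderensis var. iberica,0,0,0,0,1,0
Hedera maderensis var. maderensis,0,0,0,0,0,1
Hedera poetarum,0,0,4,0,0,0
Hedera taurica,0,0,4,0,0,0
Not identified,6,9,82,70,20,3
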