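# Model-comparison summaries from a published 454 microsatellite GBS
# experiment on Atlantic cod, used as worked examples for the AICc and
# Akaike-weight routines.  "yield" models read counts (multinomial,
# n = 90194 reads); "correspondence" models agreement between GBS and
# capillary genotypes (grouped binomial, n = 3196 genotype comparisons).
# AICc_printed is the value as printed (integers for yield, 2 d.p. for
# correspondence).
analysis,model,K,logL,AICc_printed,n
yield,PCR,3,-87627,175260,90194
yield,tails,4,-123574,247157,90194
yield,forward,6,-143882,287776,90194
yield,reverse,8,-157688,315391,90194
yield,PCR_x_tails,12,-210436,420896,90194
yield,individuals,16,-216345,432722,90194
yield,PCR_x_reverse,24,-245065,490177,90194
yield,forward_x_tails,24,-266358,532764,90194
yield,reverse_x_tails,32,-281170,562403,90194
yield,locus,53,-318574,637253,90194
yield,PCR_x_reverse_x_tails,96,-367637,735467,90194
correspondence,no_effects,1,-1724.64,3451.28,3196
correspondence,reads2,2,-1693.93,3391.87,3196
correspondence,reads3,3,-1676.04,3358.10,3196
correspondence,mst_type,5,-1693.54,3397.11,3196
correspondence,reads2_x_mst,10,-1663.76,3347.59,3196
correspondence,reads3_x_mst,15,-1644.58,3319.32,3196
correspondence,pcr_36_v_18,2,-1706.09,3416.18,3196
correspondence,pcr_3_6_18,3,-1706.08,3418.16,3196
correspondence,reads2_x_pcr,6,-1675.28,3362.58,3196
correspondence,reads3_x_pcr,9,-1658.37,3334.79,3196
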