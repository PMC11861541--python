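# pestrisk reference table v1: PPE protection factors (fraction kept off the skin)
# Body garments carry endorsed clothing-table values; gloves/headdress/mask/
# shoes/boots are declared package defaults (flagged in the audit map).
item,body_region_applicability,fraction
underwear,body,0.5
generic_clothes,body,0.7
cotton_coverall,body,0.9
nonwoven_coverall,body,0.9
hazmat_coverall,body,0.99
generic_gloves,hands,0.9
specific_gloves,hands,0.99
headdress,head,0.9
mask,face,0.9
shoes,feet,0.7
boots,feet,0.99
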