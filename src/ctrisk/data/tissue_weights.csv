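tissue,weight,is_remainder
red_bone_marrow,0.12,0
colon,0.12,0
lung,0.12,0
stomach,0.12,0
breast,0.12,0
gonads,0.08,0
bladder,0.04,0
esophagus,0.04,0
liver,0.04,0
thyroid,0.04,0
bone_surface,0.01,0
brain,0.01,0
salivary_glands,0.01,0
skin,0.01,0
adrenals,0.12,1
gall_bladder,0.12,1
heart,0.12,1
kidneys,0.12,1
pancreas,0.12,1
small_intestine,0.12,1
spleen,0.12,1
thymus,0.12,1
prostate,0.12,1
uterus,0.12,1
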