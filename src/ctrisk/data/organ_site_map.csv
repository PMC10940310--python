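organ,site,in_remainder
bladder,bladder,0
bone_surface,other,0
brain,other,0
breast,breast,0
colon,colon,0
esophagus,other,0
liver,liver,0
lung,lung,0
ovaries,ovary,0
red_bone_marrow,leukemia,0
salivary_glands,other,0
skin,other,0
stomach,stomach,0
testes,other,0
thyroid,thyroid,0
adrenals,other,1
gall_bladder,other,1
heart,other,1
kidneys,other,1
pancreas,other,1
prostate,prostate,1
small_intestine,other,1
spleen,other,1
thymus,other,1
uterus,uterus,1
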