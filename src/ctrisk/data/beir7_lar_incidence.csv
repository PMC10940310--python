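site,sex,age,value
stomach,male,0,76
stomach,male,5,65
stomach,male,10,55
stomach,male,15,46
stomach,male,20,40
stomach,male,30,28
stomach,male,40,27
stomach,male,50,25
stomach,male,60,20
stomach,male,70,14
stomach,male,80,7
colon,male,0,336
colon,male,5,285
colon,male,10,241
colon,male,15,204
colon,male,20,173
colon,male,30,125
colon,male,40,122
colon,male,50,113
colon,male,60,94
colon,male,70,65
colon,male,80,30
liver,male,0,61
liver,male,5,50
liver,male,10,43
liver,male,15,36
liver,male,20,30
liver,male,30,22
liver,male,40,21
liver,male,50,19
liver,male,60,14
liver,male,70,8
liver,male,80,3
lung,male,0,314
lung,male,5,261
lung,male,10,216
lung,male,15,180
lung,male,20,149
lung,male,30,105
lung,male,40,104
lung,male,50,101
lung,male,60,89
lung,male,70,65
lung,male,80,34
prostate,male,0,93
prostate,male,5,80
prostate,male,10,67
prostate,male,15,57
prostate,male,20,48
prostate,male,30,35
prostate,male,40,35
prostate,male,50,33
prostate,male,60,26
prostate,male,70,14
prostate,male,80,5
bladder,male,0,209
bladder,male,5,177
bladder,male,10,150
bladder,male,15,127
bladder,male,20,108
bladder,male,30,79
bladder,male,40,79
bladder,male,50,76
bladder,male,60,66
bladder,male,70,47
bladder,male,80,23
other,male,0,1123
other,male,5,672
other,male,10,503
other,male,15,394
other,male,20,312
other,male,30,198
other,male,40,172
other,male,50,140
other,male,60,98
other,male,70,57
other,male,80,23
thyroid,male,0,115
thyroid,male,5,76
thyroid,male,10,50
thyroid,male,15,33
thyroid,male,20,21
thyroid,male,30,9
thyroid,male,40,3
thyroid,male,50,1
thyroid,male,60,0.3
thyroid,male,70,0.1
thyroid,male,80,0.0
leukemia,male,0,237
leukemia,male,5,149
leukemia,male,10,120
leukemia,male,15,105
leukemia,male,20,96
leukemia,male,30,84
leukemia,male,40,84
leukemia,male,50,84
leukemia,male,60,82
leukemia,male,70,73
leukemia,male,80,48
stomach,female,0,101
stomach,female,5,85
stomach,female,10,72
stomach,female,15,61
stomach,female,20,52
stomach,female,30,36
stomach,female,40,35
stomach,female,50,32
stomach,female,60,27
stomach,female,70,19
stomach,female,80,11
colon,female,0,220
colon,female,5,187
colon,female,10,158
colon,female,15,134
colon,female,20,114
colon,female,30,82
colon,female,40,79
colon,female,50,73
colon,female,60,62
colon,female,70,45
colon,female,80,23
liver,female,0,28
liver,female,5,23
liver,female,10,20
liver,female,15,16
liver,female,20,14
liver,female,30,10
liver,female,40,10
liver,female,50,9
liver,female,60,7
liver,female,70,5
liver,female,80,2
lung,female,0,733
lung,female,5,608
lung,female,10,504
lung,female,15,417
lung,female,20,346
lung,female,30,242
lung,female,40,240
lung,female,50,230
lung,female,60,201
lung,female,70,147
lung,female,80,77
breast,female,0,1171
breast,female,5,914
breast,female,10,712
breast,female,15,553
breast,female,20,429
breast,female,30,253
breast,female,40,141
breast,female,50,70
breast,female,60,31
breast,female,70,12
breast,female,80,4
uterus,female,0,50
uterus,female,5,42
uterus,female,10,36
uterus,female,15,30
uterus,female,20,26
uterus,female,30,18
uterus,female,40,16
uterus,female,50,13
uterus,female,60,9
uterus,female,70,5
uterus,female,80,2
ovary,female,0,104
ovary,female,5,87
ovary,female,10,73
ovary,female,15,60
ovary,female,20,50
ovary,female,30,34
ovary,female,40,31
ovary,female,50,25
ovary,female,60,18
ovary,female,70,11
ovary,female,80,5
bladder,female,0,212
bladder,female,5,180
bladder,female,10,152
bladder,female,15,129
bladder,female,20,109
bladder,female,30,79
bladder,female,40,78
bladder,female,50,74
bladder,female,60,64
bladder,female,70,47
bladder,female,80,24
other,female,0,1339
other,female,5,719
other,female,10,523
other,female,15,409
other,female,20,323
other,female,30,207
other,female,40,181
other,female,50,148
other,female,60,109
other,female,70,68
other,female,80,30
thyroid,female,0,634
thyroid,female,5,419
thyroid,female,10,275
thyroid,female,15,178
thyroid,female,20,113
thyroid,female,30,41
thyroid,female,40,14
thyroid,female,50,4
thyroid,female,60,1
thyroid,female,70,0.3
thyroid,female,80,0.0
leukemia,female,0,185
leukemia,female,5,112
leukemia,female,10,86
leukemia,female,15,76
leukemia,female,20,71
leukemia,female,30,63
leukemia,female,40,62
leukemia,female,50,62
leukemia,female,60,57
leukemia,female,70,51
leukemia,female,80,37
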