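node_a	node_b	weight
frontal_l	frontal_r	1.0
frontal_l	temporal_l	1.0
frontal_l	parietal_l	1.0
frontal_l	cingulate_l	1.0
frontal_l	insula_l	1.0
frontal_l	caudate_l	1.0
frontal_l	putamen_l	1.0
frontal_l	accumbens_l	1.0
frontal_l	pallidum_l	1.0
frontal_l	thalamus_l	1.0
frontal_r	temporal_r	1.0
frontal_r	parietal_r	1.0
frontal_r	cingulate_r	1.0
frontal_r	insula_r	1.0
frontal_r	caudate_r	1.0
frontal_r	putamen_r	1.0
frontal_r	accumbens_r	1.0
frontal_r	pallidum_r	1.0
frontal_r	thalamus_r	1.0
temporal_l	temporal_r	1.0
temporal_l	parietal_l	1.0
temporal_l	occipital_l	1.0
temporal_l	insula_l	1.0
temporal_l	hippocampus_l	1.0
temporal_l	amygdala_l	1.0
temporal_r	parietal_r	1.0
temporal_r	occipital_r	1.0
temporal_r	insula_r	1.0
temporal_r	hippocampus_r	1.0
temporal_r	amygdala_r	1.0
parietal_l	parietal_r	1.0
parietal_l	occipital_l	1.0
parietal_l	cingulate_l	1.0
parietal_r	occipital_r	1.0
parietal_r	cingulate_r	1.0
occipital_l	occipital_r	1.0
cingulate_l	cingulate_r	1.0
cingulate_l	insula_l	1.0
cingulate_r	insula_r	1.0
insula_l	insula_r	1.0
hippocampus_l	hippocampus_r	1.0
hippocampus_l	amygdala_l	1.0
hippocampus_l	thalamus_l	1.0
hippocampus_r	amygdala_r	1.0
hippocampus_r	thalamus_r	1.0
amygdala_l	amygdala_r	1.0
caudate_l	caudate_r	1.0
caudate_l	putamen_l	1.0
caudate_l	accumbens_l	1.0
caudate_r	putamen_r	1.0
caudate_r	accumbens_r	1.0
putamen_l	putamen_r	1.0
putamen_l	accumbens_l	1.0
putamen_l	pallidum_l	1.0
putamen_r	accumbens_r	1.0
putamen_r	pallidum_r	1.0
accumbens_l	accumbens_r	1.0
pallidum_l	pallidum_r	1.0
pallidum_l	thalamus_l	1.0
pallidum_r	thalamus_r	1.0
thalamus_l	thalamus_r	1.0
thalamus_l	cerebellum	1.0
thalamus_r	cerebellum	1.0
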