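# Control-region mitotypes per individual (main reporting sample first).
# Carriers show the IUPAC-mixed call; the III.4 rho0 sample shows only the
# insert (U4c1) haplotype.  Non-matriline mitotypes are invented single-source
# placeholders (the published narrative states only that they were distinct).
sample_id	individual_id	tissue	range	mitotype
I.1_bone	I.1	bone	CR	73G 263G 315.1C 16223T
I.2_bone	I.2	bone	CR	16298C 72C 200G 263G 315.1C
II.1_buccal	II.1	buccal	CR	146C 263G 315.1C 16362C
II.2_intestinal	II.2	intestinal	CR	16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y 200R 263G 315.1C 499R
III.1_buccal	III.1	buccal	CR	73G 152C 263G 315.1C 16093C
III.2_blood	III.2	blood	CR	16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y 200R 263G 315.1C 499R
III.3_buccal	III.3	buccal	CR	263G 315.1C 16311C
III.4_blood	III.4	blood	CR	16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y 200R 263G 315.1C 499R
III.4_rho0	III.4	rho0_fibroblast	CR	16179T 16356C 16512C 16519C 73G 189G 195C 263G 315.1C 499A
III.5_buccal	III.5	buccal	CR	73G 146C 263G 315.1C 16189C
III.6_blood	III.6	blood	CR	16298C 72C 200G 263G 315.1C
IV.1_blood	IV.1	blood	CR	16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y 200R 263G 315.1C 499R
IV.2_buccal	IV.2	buccal	CR	152C 263G 315.1C 16519C
IV.3_blood	IV.3	blood	CR	16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y 200R 263G 315.1C 499R
IV.4_blood	IV.4	blood	CR	16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y 200R 263G 315.1C 499R
IV.5_blood	IV.5	blood	CR	16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y 200R 263G 315.1C 499R
IV.6_blood	IV.6	blood	CR	16179Y 16298Y 16356Y 16512Y 16519Y 72Y 73R 189R 195Y 200R 263G 315.1C 499R
IV.7_blood	IV.7	blood	CR	16298C 72C 200G 263G 315.1C
V.1_buccal	V.1	buccal	CR	152C 263G 315.1C 16519C
V.2_blood	V.2	blood	CR	152C 263G 315.1C 16519C
V.3_buccal	V.3	buccal	CR	152C 263G 315.1C 16519C
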