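# Tissue observations; n > 1 aggregates identical calls (clone and
# single-cell counts).  Counts printed in the published narrative are used
# verbatim (113 thrombocytes, 55+1 hair shafts, 249 I.2 bone clones); other
# batch sizes are plausible round numbers consistent with the printed
# percentages (e.g. 65/35 blood and 96/4 buccal clone splits).
individual_id	tissue	assay	call	n	is_control
II.2	intestinal	direct_sanger	mixed	1	0
III.2	blood	direct_sanger	mixed	1	0
III.2	buccal	direct_sanger	mixed	1	0
III.4	blood	direct_sanger	mixed	1	0
III.4	buccal	direct_sanger	mixed	1	0
IV.1	blood	direct_sanger	mixed	1	0
IV.1	buccal	direct_sanger	mixed	1	0
IV.3	blood	direct_sanger	mixed	1	0
IV.3	buccal	direct_sanger	mixed	1	0
IV.4	blood	direct_sanger	mixed	1	0
IV.4	buccal	direct_sanger	mixed	1	0
IV.5	blood	direct_sanger	mixed	1	0
IV.5	buccal	direct_sanger	mixed	1	0
IV.6	blood	direct_sanger	mixed	1	0
IV.6	buccal	direct_sanger	mixed	1	0
III.6	blood	direct_sanger	major_only	1	0
III.6	buccal	direct_sanger	major_only	1	0
IV.7	blood	direct_sanger	major_only	1	0
IV.7	buccal	direct_sanger	major_only	1	0
I.1	bone	direct_sanger	major_only	1	0
I.2	bone	direct_sanger	major_only	1	0
II.1	buccal	direct_sanger	major_only	1	0
III.1	buccal	direct_sanger	major_only	1	0
III.3	buccal	direct_sanger	major_only	1	0
III.5	buccal	direct_sanger	major_only	1	0
IV.2	buccal	direct_sanger	major_only	1	0
V.1	buccal	direct_sanger	major_only	1	0
V.2	blood	direct_sanger	major_only	1	0
V.3	buccal	direct_sanger	major_only	1	0
IV.3	buccal	clone	minor_only	4	0
IV.3	buccal	clone	major_only	96	0
IV.3	blood	clone	minor_only	35	0
IV.3	blood	clone	major_only	65	0
II.2	intestinal	clone	minor_only	10	0
II.2	intestinal	clone	major_only	86	0
I.2	bone	clone	major_only	249	0
I.1	bone	clone	major_only	96	0
III.6	blood	clone	major_only	96	0
IV.7	blood	clone	major_only	96	0
III.2	pbmc	single_cell	mixed	200	0
III.4	pbmc	single_cell	mixed	200	0
IV.1	pbmc	single_cell	mixed	200	0
IV.3	pbmc	single_cell	mixed	200	0
III.6	pbmc	single_cell	major_only	200	0
IV.3	thrombocyte	single_cell	major_only	113	0
III.2	hair_shaft	direct_sanger	major_only	6	0
III.4	hair_shaft	direct_sanger	major_only	6	0
III.6	hair_shaft	direct_sanger	major_only	6	0
IV.1	hair_shaft	direct_sanger	major_only	6	0
IV.3	hair_shaft	direct_sanger	major_only	7	0
IV.4	hair_shaft	direct_sanger	major_only	6	0
IV.5	hair_shaft	direct_sanger	major_only	6	0
IV.5	hair_shaft	direct_sanger	mixed	1	0
IV.6	hair_shaft	direct_sanger	major_only	6	0
IV.7	hair_shaft	direct_sanger	major_only	6	0
III.2	hair_root	direct_sanger	mixed	3	0
III.2	hair_root	direct_sanger	major_only	2	0
III.4	hair_root	direct_sanger	mixed	2	0
III.4	hair_root	direct_sanger	major_only	3	0
IV.1	hair_root	direct_sanger	mixed	3	0
IV.1	hair_root	direct_sanger	major_only	2	0
IV.3	hair_root	direct_sanger	mixed	5	0
IV.4	hair_root	direct_sanger	mixed	5	0
IV.4	hair_root	direct_sanger	major_only	1	0
IV.5	hair_root	direct_sanger	mixed	2	0
IV.5	hair_root	direct_sanger	major_only	4	0
IV.6	hair_root	direct_sanger	mixed	3	0
IV.6	hair_root	direct_sanger	major_only	2	0
III.6	hair_root	direct_sanger	major_only	5	0
IV.7	hair_root	direct_sanger	major_only	5	0
III.4	rho0_fibroblast	direct_sanger	minor_only	5	0
III.4	rho0_fibroblast	mps	minor_only	1	0
extraction_blank	other	direct_sanger	none	12	1
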