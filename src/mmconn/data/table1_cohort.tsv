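# Published per-subject characteristics (age, grip strength, ALSFRS-R) transcribed
# verbatim, including the duplicated Sub002 row; readers deduplicate by subject_id.
# sex and handedness are NOT published per subject: these columns are synthetic,
# assigned to reproduce the printed group counts (patients 11M/4F, 13R/2L;
# controls 10M/4F, 12R/2L).
subject_id	group	age	sex	handedness	grip_right	grip_left	alsfrs_r
Sub002	ALS	80	M	R	31.0	23.0	41
Sub002	ALS	80	M	R	31.0	23.0	41
Sub003	ALS	59	M	R	7.5	3.2	42
Sub004	ALS	62	M	R	8.9	20.0	37
Sub005	ALS	59	M	R	21.0	17.0	39
Sub006	ALS	68	M	R	9.8	0.0	36
Sub007	ALS	72	M	R	11.5	7.2	35
Sub008	ALS	63	M	R	18.5	15.7	38
Sub009	ALS	55	M	R	25.0	19.0	41
Sub010	ALS	63	M	R	9.8	5.0	38
Sub011	ALS	58	M	R	15.5	12.0	36
Sub012	ALS	61	M	R	10.3	8.5	37
Sub013	ALS	67	F	R	19.0	17.8	39
Sub014	ALS	71	F	R	14.7	10.5	35
Sub015	ALS	65	F	L	14.2	11.0	33
Sub016	ALS	68	F	L	12.0	10.5	32
Sub102	Control	60	M	R	34.2	33.7	48
Sub103	Control	62	M	R	33.5	32.8	48
Sub104	Control	59	M	R	35.0	34.2	48
Sub105	Control	61	M	R	31.2	30.8	48
Sub106	Control	63	M	R	32.0	31.5	48
Sub107	Control	66	M	R	29.8	30.0	48
Sub108	Control	58	M	R	33.9	34.0	48
Sub109	Control	64	M	R	30.6	30.5	48
Sub110	Control	67	M	R	31.4	30.0	48
Sub111	Control	60	M	R	34.0	33.5	48
Sub112	Control	68	F	R	29.2	28.8	48
Sub113	Control	65	F	R	32.5	32.1	48
Sub114	Control	70	F	L	30.9	30.0	48
Sub115	Control	69	F	L	33.1	32.0	48
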