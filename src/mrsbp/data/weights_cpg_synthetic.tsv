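# synthetic CpG weight fixture: stand-in EWAS effect sizes (mmHg per beta unit)
# for the 13 blood-pressure-associated CpGs; directions uniformly negative.
feature_id	trait	weight
cg23999170	sbp	-4.0
cg16246545	sbp	-18.0
cg14476101	sbp	-15.0
cg19693031	sbp	-24.0
cg08035323	sbp	-5.0
cg06690548	sbp	-27.0
cg18120259	sbp	-26.0
cg00533891	sbp	-16.0
cg17061862	sbp	-15.0
cg00574958	sbp	-86.0
cg10601624	sbp	-10.0
cg22304262	sbp	-24.0
cg02711608	sbp	-53.0
cg23999170	dbp	-4.0
cg16246545	dbp	-10.0
cg14476101	dbp	-10.0
cg19693031	dbp	-8.0
cg08035323	dbp	-3.0
cg06690548	dbp	-17.0
cg18120259	dbp	-18.0
cg00533891	dbp	-13.0
cg17061862	dbp	-10.0
cg00574958	dbp	-51.0
cg10601624	dbp	-8.0
cg22304262	dbp	-16.0
cg02711608	dbp	-34.0
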