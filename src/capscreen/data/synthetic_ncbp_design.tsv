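experiment_id	bait	target_set	condition_id	replicate	vessel	role
NCBP1_c2_r1	NCBP1	NCBP1	2	1	multiwell	case
NCBP1_c2_r2	NCBP1	NCBP1	2	2	multiwell	case
NCBP1_c2_r3	NCBP1	NCBP1	2	3	multiwell	case
NCBP1_c2_r4	NCBP1	NCBP1	2	4	multiwell	case
NCBP1_c2_ctl1	control	NCBP1	2	1	multiwell	control
NCBP1_c2_ctl2	control	NCBP1	2	2	multiwell	control
NCBP1_c2_ctl3	control	NCBP1	2	3	multiwell	control
NCBP1_c2_ctl4	control	NCBP1	2	4	multiwell	control
NCBP1_c7_r1	NCBP1	NCBP1	7	1	multiwell	case
NCBP1_c7_r2	NCBP1	NCBP1	7	2	multiwell	case
NCBP1_c7_r3	NCBP1	NCBP1	7	3	multiwell	case
NCBP1_c7_r4	NCBP1	NCBP1	7	4	multiwell	case
NCBP1_c7_ctl1	control	NCBP1	7	1	multiwell	control
NCBP1_c7_ctl2	control	NCBP1	7	2	multiwell	control
NCBP1_c7_ctl3	control	NCBP1	7	3	multiwell	control
NCBP1_c7_ctl4	control	NCBP1	7	4	multiwell	control
NCBP1_c10_r1	NCBP1	NCBP1	10	1	multiwell	case
NCBP1_c10_r2	NCBP1	NCBP1	10	2	multiwell	case
NCBP1_c10_r3	NCBP1	NCBP1	10	3	multiwell	case
NCBP1_c10_r4	NCBP1	NCBP1	10	4	multiwell	case
NCBP1_c10_ctl1	control	NCBP1	10	1	multiwell	control
NCBP1_c10_ctl2	control	NCBP1	10	2	multiwell	control
NCBP1_c10_ctl3	control	NCBP1	10	3	multiwell	control
NCBP1_c10_ctl4	control	NCBP1	10	4	multiwell	control
NCBP1_c12_r1	NCBP1	NCBP1	12	1	multiwell	case
NCBP1_c12_r2	NCBP1	NCBP1	12	2	multiwell	case
NCBP1_c12_r3	NCBP1	NCBP1	12	3	multiwell	case
NCBP1_c12_r4	NCBP1	NCBP1	12	4	multiwell	case
NCBP1_c12_ctl1	control	NCBP1	12	1	multiwell	control
NCBP1_c12_ctl2	control	NCBP1	12	2	multiwell	control
NCBP1_c12_ctl3	control	NCBP1	12	3	multiwell	control
NCBP1_c12_ctl4	control	NCBP1	12	4	multiwell	control
NCBP1_c18_r1	NCBP1	NCBP1	18	1	multiwell	case
NCBP1_c18_r2	NCBP1	NCBP1	18	2	multiwell	case
NCBP1_c18_r3	NCBP1	NCBP1	18	3	multiwell	case
NCBP1_c18_r4	NCBP1	NCBP1	18	4	multiwell	case
NCBP1_c18_ctl1	control	NCBP1	18	1	multiwell	control
NCBP1_c18_ctl2	control	NCBP1	18	2	multiwell	control
NCBP1_c18_ctl3	control	NCBP1	18	3	multiwell	control
NCBP1_c18_ctl4	control	NCBP1	18	4	multiwell	control
NCBP1_c21_r1	NCBP1	NCBP1	21	1	multiwell	case
NCBP1_c21_r2	NCBP1	NCBP1	21	2	multiwell	case
NCBP1_c21_r3	NCBP1	NCBP1	21	3	multiwell	case
NCBP1_c21_ctl1	control	NCBP1	21	1	multiwell	control
NCBP1_c21_ctl2	control	NCBP1	21	2	multiwell	control
NCBP1_c21_ctl3	control	NCBP1	21	3	multiwell	control
NCBP1_c21_ctl4	control	NCBP1	21	4	multiwell	control
NCBP2_c2_r1	NCBP2	NCBP2	2	1	multiwell	case
NCBP2_c2_r2	NCBP2	NCBP2	2	2	multiwell	case
NCBP2_c2_r3	NCBP2	NCBP2	2	3	multiwell	case
NCBP2_c2_r4	NCBP2	NCBP2	2	4	multiwell	case
NCBP2_c2_ctl1	control	NCBP2	2	1	multiwell	control
NCBP2_c2_ctl2	control	NCBP2	2	2	multiwell	control
NCBP2_c2_ctl3	control	NCBP2	2	3	multiwell	control
NCBP2_c2_ctl4	control	NCBP2	2	4	multiwell	control
NCBP2_c7_r1	NCBP2	NCBP2	7	1	multiwell	case
NCBP2_c7_r2	NCBP2	NCBP2	7	2	multiwell	case
NCBP2_c7_r3	NCBP2	NCBP2	7	3	multiwell	case
NCBP2_c7_r4	NCBP2	NCBP2	7	4	multiwell	case
NCBP2_c7_ctl1	control	NCBP2	7	1	multiwell	control
NCBP2_c7_ctl2	control	NCBP2	7	2	multiwell	control
NCBP2_c7_ctl3	control	NCBP2	7	3	multiwell	control
NCBP2_c7_ctl4	control	NCBP2	7	4	multiwell	control
NCBP2_c10_r1	NCBP2	NCBP2	10	1	multiwell	case
NCBP2_c10_r2	NCBP2	NCBP2	10	2	multiwell	case
NCBP2_c10_r3	NCBP2	NCBP2	10	3	multiwell	case
NCBP2_c10_r4	NCBP2	NCBP2	10	4	multiwell	case
NCBP2_c10_ctl1	control	NCBP2	10	1	multiwell	control
NCBP2_c10_ctl2	control	NCBP2	10	2	multiwell	control
NCBP2_c10_ctl3	control	NCBP2	10	3	multiwell	control
NCBP2_c10_ctl4	control	NCBP2	10	4	multiwell	control
NCBP2_c12_r1	NCBP2	NCBP2	12	1	multiwell	case
NCBP2_c12_r2	NCBP2	NCBP2	12	2	multiwell	case
NCBP2_c12_r3	NCBP2	NCBP2	12	3	multiwell	case
NCBP2_c12_r4	NCBP2	NCBP2	12	4	multiwell	case
NCBP2_c12_ctl1	control	NCBP2	12	1	multiwell	control
NCBP2_c12_ctl2	control	NCBP2	12	2	multiwell	control
NCBP2_c12_ctl3	control	NCBP2	12	3	multiwell	control
NCBP2_c12_ctl4	control	NCBP2	12	4	multiwell	control
NCBP2_c18_r1	NCBP2	NCBP2	18	1	multiwell	case
NCBP2_c18_r2	NCBP2	NCBP2	18	2	multiwell	case
NCBP2_c18_r3	NCBP2	NCBP2	18	3	multiwell	case
NCBP2_c18_ctl1	control	NCBP2	18	1	multiwell	control
NCBP2_c18_ctl2	control	NCBP2	18	2	multiwell	control
NCBP2_c18_ctl3	control	NCBP2	18	3	multiwell	control
NCBP2_c18_ctl4	control	NCBP2	18	4	multiwell	control
NCBP2_c21_r1	NCBP2	NCBP2	21	1	multiwell	case
NCBP2_c21_r2	NCBP2	NCBP2	21	2	multiwell	case
NCBP2_c21_r3	NCBP2	NCBP2	21	3	multiwell	case
NCBP2_c21_ctl1	control	NCBP2	21	1	multiwell	control
NCBP2_c21_ctl2	control	NCBP2	21	2	multiwell	control
NCBP2_c21_ctl3	control	NCBP2	21	3	multiwell	control
NCBP2_c21_ctl4	control	NCBP2	21	4	multiwell	control
NCBP3_c7_r1	NCBP3	NCBP3	7	1	tube	case
NCBP3_c7_r2	NCBP3	NCBP3	7	2	tube	case
NCBP3_c7_r3	NCBP3	NCBP3	7	3	tube	case
NCBP3_c7_ctl1	control	NCBP3	7	1	tube	control
NCBP3_c7_ctl2	control	NCBP3	7	2	tube	control
NCBP3_c7_ctl3	control	NCBP3	7	3	tube	control
NCBP3_c10_r1	NCBP3	NCBP3	10	1	tube	case
NCBP3_c10_r2	NCBP3	NCBP3	10	2	tube	case
NCBP3_c10_r3	NCBP3	NCBP3	10	3	tube	case
NCBP3_c10_ctl1	control	NCBP3	10	1	tube	control
NCBP3_c10_ctl2	control	NCBP3	10	2	tube	control
NCBP3_c10_ctl3	control	NCBP3	10	3	tube	control
NCBP3_c12_r1	NCBP3	NCBP3	12	1	tube	case
NCBP3_c12_r2	NCBP3	NCBP3	12	2	tube	case
NCBP3_c12_r3	NCBP3	NCBP3	12	3	tube	case
NCBP3_c12_ctl1	control	NCBP3	12	1	tube	control
NCBP3_c12_ctl2	control	NCBP3	12	2	tube	control
NCBP3_c12_ctl3	control	NCBP3	12	3	tube	control
NCBP3_c18_r1	NCBP3	NCBP3	18	1	tube	case
NCBP3_c18_r2	NCBP3	NCBP3	18	2	tube	case
NCBP3_c18_r3	NCBP3	NCBP3	18	3	tube	case
NCBP3_c18_ctl1	control	NCBP3	18	1	tube	control
NCBP3_c18_ctl2	control	NCBP3	18	2	tube	control
NCBP3_c18_ctl3	control	NCBP3	18	3	tube	control
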