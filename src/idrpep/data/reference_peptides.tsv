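# Peptides characterized against the FAM-labeled p53 CT peptide (367-393) by
# fluorescence anisotropy titration in the absence of salt. kd_um is the
# apparent dissociation constant (uM) with the SEM of the fit. contact_width
# is the design scheme for the designed peptides (1 = one-by-one, 3 =
# one-by-three); natural-protein peptides were not designed (width empty).
name	length	contact_width	sequence	kd_um	kd_sem_um
DP1	13	1	EHEEIFMESKGWR	60	40
DP2	13	1	EDEEGNDSDEHEE	23	7
DP3	16	1	DEHEEIFMESKGWRDR	550	10
DP4	16	1	DHIEDEEGNDSDEHEE	9	2
DP5	13	3	EEEEDNNDDDEEE	3.2	0.5
DP6	16	3	EEEEEDNNDDDEEEWF	1.2	0.8
Wmot2	16		WSTNGDTFLGGEDGDQ	270	40
Cul7	15		LDDYEEISAGDEGEF	180	20
WS100B	16		WLDNDGDGECDFQEFM	17	3
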