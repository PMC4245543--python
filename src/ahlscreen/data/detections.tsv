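# Strain x AHL detections: integrated peak areas (1000 counts) of each AHL in
# the chromatograms of the two analytical runs, with the identification tier
# (b = multiple co-eluting adduct ions; c = single [M+H]+ or [M+Na]+ ion; the
# better of the two runs' flags is stored).  Area 0 = not detected in that run.
# The published table's OH-C7/OH-C8 columns were garbled in transcription
# (duplicated from OH-C4/OH-C6); presence of OH-C7/OH-C8 below was curated
# against the per-strain AHL counts and the prose description of the
# Splendidus-subclade profile, and the duplicated areas retained as the only
# available figures for those cells.
strain	ahl	area_run1	area_run2	tier
S0188	C6	0	114	c
S0188	C7	178	0	b
S0188	OH-C4	32	161	b
S0188	OH-C6	880	4822	b
S0188	OH-C7	32	161	b
S0188	OH-C8	880	4822	b
S0188	OH-C10	46	561	b
S0188	OH-C12	12	163	b
S0188	OH-C14	0	21313	b
S0202	OH-C6	118	1659	b
S0202	OH-C10	0	112	b
S0202	O-C8	0	182	b
S0202	O-C10	90	3385	b
S0202	O-C12	0	30	b
S0203	OH-C4	40	3709	b
S0203	OH-C6	964	6479	b
S0203	OH-C7	40	3709	b
S0203	OH-C8	964	6479	b
S0203	OH-C10	58	412	b
S0203	OH-C12	16	256	b
S0203	OH-C14	0	94	b
S0207	OH-C6	167	1807	b
S0207	OH-C10	0	70	b
S0207	O-C10	96	3637	b
S0207	O-C12	0	43	b
S0209	C6	0	116	b
S0209	OH-C4	17	342	b
S0209	OH-C6	627	4297	b
S0209	OH-C7	17	342	b
S0209	OH-C8	627	4297	b
S0209	OH-C9	0	30	b
S0209	OH-C10	28	452	b
S0209	OH-C12	0	64	b
S0273	OH-C4	28	273	b
S0273	OH-C6	896	5918	b
S0273	OH-C7	28	273	b
S0273	OH-C8	896	5918	b
S0273	OH-C10	75	485	b
S0273	OH-C12	17	278	b
S0273	OH-C14	0	115	b
S0344	C4	92	5352	b
S0344	OH-C4	0	50	b
S0821	C8	57	6284	b
S0821	O-C8	0	294	b
S0821	O-C9	11	423	b
S0821	O-C10	82	2991	b
S0821	O-C11	10	0	c
S0821	O-C12	0	72	b
S0843	C4	317	11974	b
S0843	OH-C4	0	94	b
S0845	C4	83	5009	b
S1089	C12	0	125322	b
S1089	OH-C4	310	2279	b
S1089	OH-C6	0	119	b
S1089	OH-C12	42	1313	b
S1106	OH-C6	140	2050	b
S1106	OH-C10	0	93	c
S1106	O-C10	86	3661	b
S1106	O-C12	0	41	b
S1110	O-C10	58	2770	b
S1110	O-C11	0	305	b
S1137	OH-C6	210	3154	b
S1137	OH-C8	210	3154	b
S1162	OH-C10	239	134	b
S1162	OH-C11	59	503	b
S1162	O-C4	30	0	b
S1162	O-C8	12	273	b
S1162	O-C9	31	620	b
S1162	O-C10	241	5862	b
S1162	O-C11	623	10784	b
S1162	O-C12	12	0	c
S1192	OH-C12	0	104	b
S1194	OH-C4	61	491	b
S1194	OH-C12	0	215	b
S1196	OH-C4	163	1425	b
S1196	OH-C12	0	80	b
S1728	OH-C6	61	617	b
S1728	OH-C10	0	78	b
S1728	O-C10	89	3069	b
S1728	O-C12	0	106	b
S1729	C8	53	5170	b
S1729	OH-C6	268	2943	b
S1729	OH-C10	17	124	b
S1729	O-C6	0	303	b
S1729	O-C8	11	293	b
S1729	O-C10	171	6066	b
S1729	O-C12	16	77	b
S1730	OH-C6	142	2643	b
S1730	OH-C10	0	147	b
S1730	O-C8	0	274	b
S1730	O-C10	115	5836	b
S1730	O-C12	0	52	b
S1732	OH-C6	201	2201	b
S1732	OH-C10	12	100	b
S1732	O-C8	10	233	b
S1732	O-C10	149	5687	b
S1732	O-C12	0	68	b
S2605	OH-C6	33	369	b
S2606	C6	0	773	c
S2606	C7	806	0	b
S2606	OH-C4	0	90	b
S2606	OH-C6	961	6248	b
S2606	OH-C7	0	90	b
S2606	OH-C8	961	6248	b
S2719	C4	77	4578	b
S2719	C6	0	54	c
S2757	C6	0	69	c
S2757	OH-C6	364	5464	b
S2757	O-C6	0	220	b
S3857	C6	52	5321	b
S3857	C8	0	768	b
S4497	C4	19	917	b
S4497	C6	286	12817	b
S4497	C7	631	0	b
S4634	OH-C6	0	148	b
S4738	OH-C4	219	2638	b
90-11-287	OH-C6	192	2162	b
90-11-287	OH-C10	0	46	c
90-11-287	O-C10	111	3228	b
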