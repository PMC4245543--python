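# 32 AHL-positive Vibrionaceae strains from a global culture collection plus
# the V. anguillarum reference strain 90-11-287 (no isolation site recorded).
# species: fur-gene species assignment; clade: Sawabe-scheme clade label;
# medium: LB broth at 1% (LB10) or 2% (LB20) NaCl.
strain	species	clade	latitude	longitude	medium	reference
S0188	V. splendidus	Splendidus	62.03815	-9.99592	LB20	0
S0202	V. anguillarum	Anguillarum	62.03815	-9.99592	LB10	0
S0203	V. splendidus	Splendidus	62.03815	-9.99592	LB20	0
S0207	V. anguillarum	Anguillarum	62.16527	-16.5731	LB10	0
S0209	V. splendidus	Splendidus	62.16527	-16.5731	LB20	0
S0273	V. splendidus	Splendidus	62.2569	-20.8819	LB20	0
S0344	V. pacinii	Pacinii	66.7494	-53.8954	LB10	0
S0787	V. shilonii	Mediterranei	33.7571	-25.4239	LB10	0
S0821	V. fluvialis	Cholerae	23.0918	-24.0417	LB10	0
S0843	V. brasiliensis	Orientalis	12.20592	-21.0234	LB20	0
S0845	V. brasiliensis	Orientalis	12.20592	-21.0234	LB10	0
S1073	V. nigripulchritudo	Nigripulchritudo	1.6207	-10.5021	LB20	0
S1089	V. campbelli	Harveyi	4.570467	-1.72975	LB10	0
S1106	V. anguillarum	Anguillarum	4.570467	-1.72975	LB10	0
S1110	V. fluvialis	Cholerae	4.570467	-1.72975	LB10	0
S1137	V. splendidus	Splendidus	4.9119	-0.3376	LB10	0
S1162	V. fluvialis	Cholerae	4.570467	-1.72975	LB10	0
S1192	P. angustum	Photobacterium	4.570467	-1.72975	LB10	0
S1194	V. campbelli	Harveyi	4.570467	-1.72975	LB10	0
S1196	V. campbelli	Harveyi	4.570467	-1.72975	LB10	0
S1728	V. anguillarum	Anguillarum	-19.7461	114.8573	LB10	0
S1729	V. anguillarum	Anguillarum	-19.7461	114.8573	LB10	0
S1730	V. anguillarum	Anguillarum	-19.7461	114.8573	LB10	0
S1732	V. anguillarum	Anguillarum	-19.7461	114.8573	LB10	0
S2605	V. tubiashii	Orientalis	-10.3454	157.7956	LB10	0
S2606	V. tubiashii	Orientalis	-10.3454	157.7956	LB20	0
S2719	V. brasiliensis	Orientalis	-8.1005	156.8451	LB10	0
S2757	V. tubiashii	Orientalis	-15.2329	156.665	LB10	0
S3857	V. rotiferianus	Harveyi	-14.159	-77.4004	LB10	0
S4497	V. rotiferianus	Harveyi	24.9963	-67.0246	LB20	0
S4634	V. splendidus	Splendidus	43.0309	-66.2774	LB10	0
S4738	V. splendidus	Splendidus	58.8041	-3.0564	LB20	0
90-11-287	V. anguillarum	Anguillarum			LB10	1
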