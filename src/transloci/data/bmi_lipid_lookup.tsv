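transferable	trait	rsid	chrom	pos	annotation	beta	se	p
no	HDL	rs11755393	6	34824636	UHRF1BP1	-0.025	0.002	9.8e-48
no	HDL	rs1178977	7	72856430	BAZ1B	-0.010	0.002	3.1e-6
no	HDL	rs4731702	7	130433384	KLF14	0.008	0.002	3e-7
no	HDL	rs2954033	8	126493746	NSMCE2	-0.010	0.002	6.4e-8
no	LDL	rs4245791	2	44074431	ABCG8	0.002	0.002	0.22
no	LDL	rs3846662	5	74651084	HMGCR	0.020	0.002	1.9e-35
no	LDL	rs2737229	8	116648565	TRPS1	0.014	0.002	1.9e-15
no	LDL	rs635634	9	136155000	IL6R	0.005	0.002	0.03
no	LDL	rs2000999	16	72108093	HPR	0.011	0.002	8.6e-8
no	TG	rs1260326	2	27730940	GCKR	-0.011	0.002	1.2e-10
no	TG	rs2943641	2	227093745	IRS1	0.006	0.002	5.8e-4
no	TG	rs6905288	6	43758873	VEGFA	-0.010	0.002	1.9e-9
no	TG	rs11820589	11	116633862	APOA5	-0.003	0.003	0.41
no	TG	rs58542926	19	19379549	TM6SF2	-0.003	0.003	0.33
yes	HDL	rs643531	9	15296034	TTC39B	0.000	0.002	0.92
yes	HDL	rs1800588	15	58723675	LIPC	-0.002	0.002	0.25
yes	HDL	rs3764261	16	56993324	CETP	-0.002	0.002	0.39
yes	HDL	rs16942887	16	67928042	PSKH1	-0.005	0.003	0.06
yes	LDL	rs12740374	1	109817590	CELSR2	0.003	0.002	0.18
yes	LDL	rs1367117	2	21263900	APOB	-0.002	0.002	0.19
yes	LDL	rs6511720	19	11202306	LDLR	0.006	0.003	0.03
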