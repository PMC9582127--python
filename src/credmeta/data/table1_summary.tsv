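gene	variant	alleles	disease	stratum	datasets	cases	controls	genetic_model	effect_model	or	ci_low	ci_high	p	i_squared	p_q	venice_code	fprp	credibility
CHRNA3	rs1051730	A vs. G	COPD	Overall	4	1618	1909	allelic	fixed	1.630	1.293	2.054	<0.001	0.0	0.897	BAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	COPD	Overall	4	1618	1909	dominant	fixed	1.662	1.300	2.124	<0.001	0.0	0.877	BAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	COPD	Overall	4	1618	1909	recessive	random	2.433	0.737	8.033	0.144	0.0	0.425
CHRNA3	rs1051730	A vs. G	COPD	Asian	3	1501	1717	allelic	fixed	1.591	1.204	2.103	0.001	0.0	0.780	BAA	0.001	Strong
CHRNA3	rs1051730	A vs. G	COPD	Asian	3	1501	1717	dominant	fixed	1.625	1.222	2.160	0.001	0.0	0.748	BAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	COPD	Asian	3	1501	1717	recessive	random	1.017	0.106	9.793	0.988	0.0	0.341
CHRNA3	rs6495309	T vs. C	COPD	Asian	3	1917	2068	allelic	fixed	0.830	0.759	0.906	<0.001	25.9	0.259	ABA	<0.001	Strong
CHRNA3	rs6495309	T vs. C	COPD	Asian	3	1917	2068	dominant	fixed	0.736	0.644	0.842	<0.001	0.0	0.892	AAA	<0.001	Strong
CHRNA3	rs6495309	T vs. C	COPD	Asian	3	1917	2068	recessive	random	0.830	0.637	1.081	0.166	64.7	0.059
CHRNA5	rs16969968	A vs. G	COPD	Overall	6	3126	7685	allelic	fixed	1.307	1.205	1.417	<0.001	0.0	0.471	AAC	<0.001	Moderate
CHRNA5	rs16969968	A vs. G	COPD	Overall	6	3126	7685	dominant	fixed	1.413	1.268	1.573	<0.001	0.0	0.687	AAC	<0.001	Moderate
CHRNA5	rs16969968	A vs. G	COPD	Overall	6	3126	7685	recessive	fixed	1.370	1.154	1.625	<0.001	0.0	0.713	BAA	<0.001	Strong
CHRNA5	rs16969968	A vs. G	COPD	Asian	3	1501	1717	allelic	fixed	1.591	1.204	2.103	0.001	0.0	0.780	BAA	0.001	Strong
CHRNA5	rs16969968	A vs. G	COPD	Asian	3	1501	1717	dominant	fixed	1.625	1.222	2.160	0.001	0.0	0.748	BAA	<0.001	Strong
CHRNA5	rs16969968	A vs. G	COPD	Asian	3	1501	1717	recessive	fixed	1.017	0.143	7.229	0.987	0.0	0.341
CHRNA3	rs1051730	A vs. G	LC	Overall	11	7657	7515	allelic	fixed	1.348	1.276	1.424	<0.001	37.0	0.103	ABA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	LC	Overall	11	7657	7515	dominant	fixed	1.446	1.342	1.559	<0.001	10.0	0.349	AAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	LC	Overall	11	7657	7515	recessive	fixed	1.519	1.356	1.700	<0.001	0.0	0.582	AAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	LC	Asian	3	1834	1460	allelic	fixed	2.280	1.626	3.197	<0.001	0.0	0.978	BAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	LC	Asian	3	1834	1460	dominant	fixed	2.329	1.649	3.291	<0.001	0.0	0.982	BAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	LC	Asian	3	1834	1460	recessive	random	2.249	0.234	21.659	0.483	Na	Na
CHRNA3	rs1051730	A vs. G	LC	Caucasian	6	3492	5434	allelic	fixed	1.313	1.240	1.390	<0.001	0.0	0.611	AAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	LC	Caucasian	6	3492	5434	dominant	fixed	1.389	1.283	1.504	<0.001	0.0	0.886	AAA	<0.001	Strong
CHRNA3	rs1051730	A vs. G	LC	Caucasian	6	3492	5434	recessive	fixed	1.506	1.344	1.688	<0.001	8.0	0.365	AAA	<0.001	Strong
CHRNA3	rs12914385	T vs. C	LC	Overall	4	10037	4443	allelic	random	1.096	0.799	1.505	0.569	96.7	<0.001
CHRNA3	rs12914385	T vs. C	LC	Overall	4	10037	4443	dominant	random	1.101	0.712	1.703	0.665	96.6	<0.001
CHRNA3	rs12914385	T vs. C	LC	Overall	4	10037	4443	recessive	random	1.206	0.839	1.733	0.312	89.4	<0.001
CHRNA3	rs12914385	T vs. C	LC	Caucasian	3	8514	2900	allelic	random	1.264	1.053	1.517	0.012	84.4	0.002	ACA	0.012	Moderate
CHRNA3	rs12914385	T vs. C	LC	Caucasian	3	8514	2900	dominant	random	1.458	1.331	1.596	0.014	81.5	0.004	ACA	<0.001	Moderate
CHRNA3	rs12914385	T vs. C	LC	Caucasian	3	8514	2900	recessive	random	1.449	1.134	1.851	0.003	66.5	0.051	ACA	0.003	Moderate
CHRNA3	rs3743073	T vs. G	LC	Overall	3	1391	1500	allelic	random	0.785	0.546	1.129	0.191	91.3	<0.001
CHRNA3	rs3743073	T vs. G	LC	Overall	3	1391	1500	dominant	random	0.755	0.410	1.392	0.368	90.7	<0.001
CHRNA3	rs3743073	T vs. G	LC	Overall	3	1391	1500	recessive	random	0.729	0.504	1.056	0.094	80.0	0.007
CHRNA3	rs578776	A vs. G	LC	Overall	3	1254	2009	allelic	fixed	0.868	0.773	0.976	0.018	0.0	0.908	AAA	0.018	Strong
CHRNA3	rs578776	A vs. G	LC	Overall	3	1254	2009	dominant	fixed	0.841	0.722	0.979	0.026	0.0	0.937	AAA	0.025	Strong
CHRNA3	rs578776	A vs. G	LC	Overall	3	1254	2009	recessive	random	0.839	0.655	1.073	0.162	0.0	0.944
CHRNA3	rs6495309	T vs. C	LC	Asian	3	1865	1983	allelic	fixed	0.770	0.704	0.843	<0.001	0.0	0.400	AAA	<0.001	Strong
CHRNA3	rs6495309	T vs. C	LC	Asian	3	1865	1983	dominant	fixed	0.736	0.642	0.843	<0.001	0.0	0.749	AAA	<0.001	Strong
CHRNA3	rs6495309	T vs. C	LC	Asian	3	1865	1983	recessive	fixed	0.680	0.580	0.797	<0.001	0.0	0.373	BAA	<0.001	Strong
CHRNA3	rs8042374	G vs. A	LC	Caucasian	3	8501	2920	allelic	random	0.814	0.703	0.941	0.006	67.7	0.045	ACC	0.005	Moderate
CHRNA3	rs8042374	G vs. A	LC	Caucasian	3	8501	2920	dominant	fixed	0.763	0.697	0.834	<0.001	47.3	0.150	ABC	<0.001	Moderate
CHRNA3	rs8042374	G vs. A	LC	Caucasian	3	8501	2920	recessive	random	0.715	0.503	1.016	0.061	62.6	0.069
CHRNA3	rs938682	A vs. G	LC	Overall	3	4958	2575	allelic	fixed	1.239	1.131	1.357	<0.001	0.0	0.384	AAC	<0.001	Moderate
CHRNA3	rs938682	A vs. G	LC	Overall	3	4958	2575	dominant	random	1.233	0.829	1.834	0.301	61.8	0.073
CHRNA3	rs938682	A vs. G	LC	Overall	3	4958	2575	recessive	fixed	1.295	1.158	1.447	<0.001	0.0	0.932	AAA	<0.001	Strong
CHRNA5	rs16969968	A vs. G	LC	Overall	14	22794	82907	allelic	fixed	1.293	1.260	1.328	<0.001	25.1	0.183	ABA	<0.001	Strong
CHRNA5	rs16969968	A vs. G	LC	Overall	14	22794	82907	dominant	fixed	1.374	1.324	1.426	<0.001	34.4	0.100	ABA	<0.001	Strong
CHRNA5	rs16969968	A vs. G	LC	Overall	14	22794	82907	recessive	fixed	1.445	1.372	1.522	<0.001	0.0	0.568	AAA	<0.001	Strong
CHRNA5	rs16969968	A vs. G	LC	Caucasian	12	21035	80599	allelic	fixed	1.298	1.264	1.333	<0.001	0.0	0.575	AAC	<0.001	Moderate
CHRNA5	rs16969968	A vs. G	LC	Caucasian	12	21035	80599	dominant	fixed	1.384	1.333	1.437	<0.001	0.0	0.495	AAA	<0.001	Strong
CHRNA5	rs16969968	A vs. G	LC	Caucasian	12	21035	80599	recessive	fixed	1.447	1.374	1.524	<0.001	0.0	0.540	AAC	<0.001	Moderate
CHRNA5	rs588765	C vs. T	LC	Caucasian	4	5851	7321	allelic	fixed	1.124	1.069	1.182	<0.001	0.0	0.890	AAC	<0.001	Moderate
CHRNA5	rs588765	C vs. T	LC	Caucasian	4	5851	7321	dominant	fixed	1.122	1.020	1.234	0.018	0.0	0.724	AAC	0.018	Moderate
CHRNA5	rs588765	C vs. T	LC	Caucasian	4	5851	7321	recessive	fixed	1.192	1.109	1.280	<0.001	0.0	0.898	AAA	<0.001	Strong
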