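gene_id	illumina_ratio	qpcr_ratio_12daa	p_12daa	qpcr_ratio_22daa	p_22daa
Isogroup10136	8.745	4.976	0.004	6.472	0.000
Isogroup08662	5.887	2.110	0.018	2.021	0.001
Isogroup14133	3.303	0.983	0.955	1.208	0.780
Isogroup10811	3.226	2.183	0.034	4.795	0.005
Isogroup12718	2.917	1.670	0.189	1.800	0.018
Isogroup06043	2.797	1.761	0.040	2.088	0.045
Isogroup02905	2.292	1.349	0.192	2.800	0.008
Isogroup03083	2.218	0.839	0.638	1.904	0.108
Isogroup10053	2.190	1.017	0.920	1.094	0.572
Isogroup01211	2.052	0.806	0.506	1.582	0.119
Isogroup11278	0.471	0.764	0.180	0.726	0.114
Isogroup05843	0.448	0.852	0.316	0.827	0.068
Isogroup03470	0.445	0.863	0.271	0.845	0.063
Isogroup13287	0.422	1.012	0.942	0.853	0.427
Isogroup13088	0.393	0.698	0.050	0.843	0.492
Isogroup06482	0.365	0.916	0.461	0.924	0.605
Isogroup10940	0.333	0.739	0.018	0.631	0.917
Isogroup10620	0.272	0.716	0.029	1.068	0.732
Isogroup13722	0.267	0.606	0.005	0.522	0.336
Isogroup07898	0.254	0.970	0.816	0.882	0.325
Isogroup06574	0.237	0.973	0.782	0.759	0.063
Isogroup07736	0.199	0.620	0.015	0.975	0.912
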