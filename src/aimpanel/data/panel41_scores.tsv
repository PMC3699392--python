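locus_id	I_n	in31	Africa-Americas	Africa-CSAsia	Africa-EAsia	Africa-Europe	Africa-MiddleEast	Africa-Oceania	Americas-CSAsia	Americas-EAsia	Americas-Europe	Americas-MiddleEast	Americas-Oceania	CSAsia-EAsia	CSAsia-Europe	CSAsia-MiddleEast	CSAsia-Oceania	EAsia-Europe	EAsia-MiddleEast	EAsia-Oceania	Europe-MiddleEast	Europe-Oceania	MiddleEast-Oceania
rs1834640	0.406	1	0.367	0.838	0.090	0.945	0.918	0.004	0.471	0.277	0.578	0.551	0.371	0.749	0.107	0.080	0.842	0.855	0.828	0.093	0.027	0.949	0.921
rs9809818	0.364	0	0.811	0.355	0.822	0.057	0.079	0.972	0.455	0.012	0.754	0.731	0.162	0.467	0.299	0.276	0.617	0.765	0.743	0.150	0.023	0.916	0.893
rs310644	0.352	1	0.909	0.741	0.925	0.899	0.812	0.063	0.168	0.016	0.010	0.097	0.846	0.184	0.158	0.071	0.678	0.026	0.114	0.862	0.087	0.836	0.749
rs1834619	0.334	0	0.953	0.280	0.723	0.073	0.028	0.714	0.673	0.230	0.880	0.926	0.239	0.443	0.207	0.252	0.434	0.650	0.695	0.008	0.045	0.642	0.687
rs1572018	0.320	0	0.930	0.718	0.340	0.877	0.724	0.036	0.212	0.590	0.053	0.206	0.894	0.378	0.159	0.006	0.682	0.537	0.384	0.304	0.153	0.841	0.688
rs7226659	0.318	0	0.415	0.055	0.575	0.002	0.019	0.950	0.360	0.160	0.417	0.396	0.535	0.520	0.057	0.036	0.894	0.577	0.556	0.375	0.021	0.952	0.931
rs260714	0.302	0	0.064	0.589	0.107	0.705	0.601	0.164	0.653	0.043	0.769	0.665	0.099	0.696	0.116	0.012	0.752	0.812	0.708	0.056	0.104	0.868	0.764
rs4918664	0.287	1	0.855	0.285	0.869	0.147	0.038	0.174	0.569	0.014	0.708	0.816	0.681	0.583	0.138	0.247	0.111	0.722	0.830	0.695	0.109	0.027	0.136
rs4471745	0.284	1	0.097	0.003	0.023	0.050	0.104	0.869	0.094	0.120	0.048	0.006	0.967	0.025	0.047	0.101	0.872	0.072	0.126	0.847	0.054	0.919	0.973
rs11725412	0.272	1	0.704	0.047	0.432	0.186	0.243	0.421	0.751	0.272	0.890	0.947	0.284	0.479	0.138	0.196	0.468	0.617	0.675	0.011	0.058	0.606	0.664
rs3098610	0.271	1	0.761	0.328	0.849	0.265	0.399	0.980	0.433	0.088	0.496	0.362	0.219	0.521	0.063	0.071	0.652	0.584	0.450	0.131	0.134	0.715	0.581
rs4664511	0.268	1	0.568	0.143	0.502	0.043	0.090	0.833	0.424	0.066	0.611	0.658	0.266	0.358	0.187	0.233	0.690	0.545	0.591	0.332	0.047	0.877	0.923
rs10079352	0.267	1	0.975	0.540	0.957	0.459	0.312	0.419	0.434	0.017	0.516	0.662	0.556	0.417	0.082	0.228	0.121	0.499	0.645	0.539	0.146	0.040	0.107
rs2166624	0.262	1	0.977	0.323	0.430	0.383	0.224	0.000	0.654	0.546	0.594	0.753	0.977	0.108	0.060	0.099	0.323	0.047	0.206	0.430	0.159	0.383	0.224
rs12498138	0.247	1	0.906	0.070	0.090	0.060	0.040	0.089	0.836	0.817	0.846	0.866	0.817	0.020	0.010	0.030	0.019	0.029	0.050	0.000	0.020	0.029	0.049
rs7251928	0.245	1	0.966	0.778	0.942	0.741	0.662	0.787	0.188	0.024	0.225	0.304	0.179	0.164	0.037	0.116	0.009	0.201	0.280	0.155	0.079	0.046	0.125
rs6990312	0.244	1	0.457	0.516	0.787	0.621	0.505	0.166	0.060	0.330	0.164	0.048	0.623	0.271	0.104	0.012	0.683	0.166	0.282	0.953	0.116	0.787	0.671
rs3823159	0.242	1	0.477	0.859	0.745	0.904	0.815	0.371	0.382	0.268	0.427	0.338	0.106	0.114	0.044	0.045	0.488	0.158	0.070	0.374	0.089	0.533	0.444
rs2024566	0.236	1	0.903	0.257	0.012	0.218	0.239	0.056	0.647	0.891	0.685	0.664	0.959	0.245	0.039	0.017	0.312	0.206	0.228	0.067	0.022	0.273	0.295
rs7722456	0.235	1	0.362	0.268	0.351	0.175	0.178	0.569	0.094	0.011	0.187	0.184	0.931	0.084	0.093	0.089	0.836	0.176	0.173	0.920	0.003	0.744	0.747
rs9880567	0.232	1	0.567	0.326	0.441	0.307	0.353	0.402	0.241	0.126	0.260	0.214	0.969	0.115	0.019	0.027	0.728	0.134	0.088	0.843	0.046	0.709	0.755
rs842639	0.231	1	0.706	0.340	0.603	0.014	0.062	0.674	0.366	0.103	0.692	0.768	0.032	0.263	0.326	0.402	0.334	0.589	0.665	0.071	0.076	0.660	0.735
rs10497191	0.230	1	0.883	0.858	0.893	0.822	0.768	0.889	0.024	0.010	0.061	0.115	0.007	0.035	0.037	0.091	0.031	0.072	0.126	0.004	0.054	0.068	0.122
rs734241	0.227	1	0.899	0.211	0.311	0.003	0.035	0.464	0.688	0.589	0.896	0.864	0.435	0.100	0.208	0.176	0.253	0.308	0.276	0.153	0.032	0.461	0.429
rs735480	0.224	0	0.459	0.755	0.597	0.895	0.815	0.205	0.296	0.138	0.436	0.356	0.255	0.158	0.140	0.060	0.551	0.298	0.218	0.393	0.080	0.691	0.611
rs2593595	0.218	1	0.615	0.688	0.805	0.753	0.683	0.990	0.073	0.189	0.138	0.068	0.375	0.117	0.065	0.004	0.303	0.052	0.121	0.186	0.069	0.237	0.307
rs2717329	0.213	1	0.762	0.603	0.710	0.759	0.520	0.980	0.159	0.052	0.003	0.241	0.219	0.107	0.156	0.083	0.378	0.049	0.189	0.271	0.239	0.222	0.460
rs10961366	0.213	0	0.019	0.254	0.023	0.254	0.278	0.623	0.235	0.042	0.235	0.259	0.642	0.277	0.000	0.024	0.876	0.277	0.301	0.600	0.024	0.877	0.900
rs1557553	0.207	1	0.887	0.080	0.273	0.085	0.045	0.195	0.806	0.614	0.802	0.842	0.692	0.193	0.004	0.036	0.114	0.188	0.228	0.078	0.040	0.110	0.150
rs4741658	0.202	0	0.742	0.458	0.774	0.225	0.117	0.630	0.285	0.032	0.518	0.626	0.113	0.317	0.233	0.341	0.172	0.549	0.658	0.144	0.108	0.405	0.513
rs2196051	0.202	1	0.012	0.228	0.002	0.645	0.493	0.020	0.216	0.014	0.633	0.481	0.031	0.230	0.417	0.265	0.248	0.647	0.495	0.018	0.152	0.665	0.512
rs6737672	0.199	1	0.977	0.585	0.620	0.516	0.561	0.321	0.392	0.357	0.461	0.415	0.655	0.035	0.069	0.024	0.264	0.104	0.059	0.299	0.046	0.194	0.240
rs10877030	0.185	1	0.472	0.082	0.231	0.197	0.318	0.460	0.390	0.241	0.669	0.790	0.012	0.149	0.279	0.400	0.378	0.428	0.549	0.229	0.122	0.657	0.779
rs7837234	0.162	1	0.113	0.003	0.271	0.039	0.044	0.619	0.110	0.158	0.152	0.069	0.732	0.268	0.042	0.041	0.622	0.310	0.227	0.890	0.083	0.580	0.663
rs4907251	0.157	1	0.843	0.550	0.528	0.205	0.242	0.475	0.292	0.315	0.638	0.600	0.367	0.023	0.346	0.308	0.075	0.323	0.286	0.052	0.038	0.271	0.233
rs1863086	0.149	1	0.658	0.133	0.214	0.255	0.116	0.310	0.525	0.872	0.403	0.542	0.348	0.347	0.122	0.017	0.177	0.469	0.330	0.524	0.139	0.055	0.194
rs310362	0.147	0	0.763	0.476	0.533	0.627	0.279	0.751	0.287	0.229	0.136	0.484	0.011	0.058	0.151	0.197	0.276	0.094	0.255	0.218	0.349	0.124	0.473
rs4705360	0.139	1	0.701	0.300	0.397	0.047	0.011	0.419	0.401	0.304	0.654	0.712	0.282	0.097	0.253	0.312	0.119	0.350	0.409	0.021	0.058	0.372	0.430
rs4833103	0.110	1	0.016	0.038	0.009	0.449	0.104	0.000	0.022	0.007	0.434	0.089	0.016	0.029	0.412	0.067	0.038	0.441	0.096	0.009	0.345	0.449	0.104
rs359955	0.090	0	0.455	0.533	0.613	0.639	0.298	0.410	0.078	0.158	0.183	0.157	0.046	0.080	0.106	0.235	0.124	0.026	0.315	0.204	0.341	0.229	0.111
rs12878166	0.078	1	0.137	0.220	0.413	0.098	0.259	0.038	0.356	0.549	0.039	0.396	0.174	0.193	0.317	0.039	0.182	0.510	0.154	0.375	0.356	0.135	0.221
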