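analyte	intensity	p_value	differential_intensity	relative_fold_change	log2_fc	n_hits
Angiogenin	0.3199	0.0028	-0.1331	-0.2938	-0.5019	5
BDNF	0.4531	0.4293	-0.0297	-0.0616	-0.0917	1
BLC (CXCL13)	0.0715	0.1307	-0.0895	-0.5558	-1.1708	0
Ck beta 8-1 (CCL23)	0.0322	0.1344	-0.1055	-0.7660	-2.0955	0
EGF	0.0100	0.0904	-0.1008	-0.9097	-3.4698	0
ENA-78 (CXCL5)	0.0464	0.1580	-0.0459	-0.4973	-0.9922	0
Eotaxin-1 (CCL11)	0.0208	0.1268	-0.0918	-0.8155	-2.4387	0
Eotaxin-2 (CCL24)	0.0100	0.1782	-0.0778	-0.8861	-3.1341	0
Eotaxin-3 (CCL26)	0.0100	0.0456	-0.0325	-0.7647	-2.0872	2
FGF-4	0.1738	0.4402	0.0288	0.1987	0.2614	0
FGF-6	0.1882	0.0561	0.0600	0.4679	0.5538	1
FGF-7 (KGF)	0.0997	0.1638	0.0436	0.7776	0.8300	4
FGF-9	0.2474	0.5959	0.0315	0.1460	0.1966	1
FLT-3 Ligand	0.1239	0.5896	-0.0123	-0.0906	-0.1370	0
Fractalkine (CX3CL1)	0.1396	0.1526	-0.0589	-0.2969	-0.5082	0
G-CSF	0.0100	0.1813	-0.0391	-0.7962	-2.2948	0
GDNF	0.0393	0.0590	-0.1486	-0.7907	-2.2565	3
GM-CSF	0.0100	0.0739	-0.0320	-0.7621	-2.0716	0
GPC-2 (CXCL6)	0.0466	0.0889	-0.1052	-0.6931	-1.7041	0
GRO a/b/g	0.1577	0.0313	-0.1014	-0.3913	-0.7162	2
GRO alpha (CXCL1)	0.0100	0.1253	-0.0267	-0.7279	-1.8775	0
HGF	0.0100	0.1463	-0.0363	-0.7842	-2.2124	0
I-309 (CCL1)	0.0338	0.5121	-0.0289	-0.4605	-0.8904	0
IFN-gamma	0.1881	0.9113	0.0051	0.0281	0.0400	0
IGF-1	0.0100	0.0384	-0.0750	-0.8824	-3.0874	3
IGFBP-1	0.0100	0.2575	-0.0365	-0.7851	-2.2180	0
IGFBP-2	0.0253	0.0948	-0.0776	-0.7542	-2.0247	0
IGFBP-3	0.1122	0.9345	0.0010	0.0092	0.0133	0
IGFBP-4	0.1027	0.2169	-0.0222	-0.1774	-0.2817	0
IL-1 alpha (IL-1 F1)	0.0770	0.8593	-0.0083	-0.0977	-0.1483	0
IL-1 beta (IL-1 F2)	0.2268	0.3119	0.0318	0.1633	0.2182	0
IL-10	0.0100	NA	0.0000	0.0000	0.0000	0
IL-12 (p40/p70)	0.1481	0.0983	-0.0269	-0.1536	-0.2406	0
IL-13	0.0654	0.3267	0.0323	0.9763	0.9828	1
IL-15	0.2774	0.2844	0.0478	0.2081	0.2727	2
IL-16	0.1368	0.2513	-0.0505	-0.2697	-0.4535	0
IL-2	0.1239	0.5033	0.0271	0.2799	0.3561	0
IL-3	0.1964	0.6411	0.0224	0.1290	0.1751	0
IL-4	0.0869	0.2814	-0.0215	-0.1984	-0.3191	0
IL-5	0.0100	0.1043	-0.0978	-0.9073	-3.4306	3
IL-6	1.8106	0.5854	-0.0546	-0.0293	-0.0429	1
IL-7	0.0100	0.0949	-0.1245	-0.9256	-3.7491	4
IL-8 (CXCL8)	1.0915	0.9680	0.0061	0.0057	0.0082	1
IP-10 (CXCL10)	0.6526	0.2375	0.0728	0.1256	0.1707	4
Leptin	0.1577	0.2038	-0.0463	-0.2268	-0.3711	0
LIF	0.3174	0.5290	0.0531	0.2011	0.2643	4
LIGHT (TNFSF14)	0.1716	0.7360	-0.0059	-0.0331	-0.0486	0
MCP-1 (CCL2)	1.5040	0.1989	0.1576	0.1170	0.1596	4
MCP-2 (CCL8)	0.0707	0.0456	-0.0596	-0.4575	-0.8824	1
MCP-3 (CCL7)	0.0100	0.0017	-0.0681	-0.8719	-2.9649	2
MCP-4 (CCL13)	0.0676	0.1183	-0.0606	-0.4727	-0.9232	0
M-CSF	0.0577	0.0341	-0.1840	-0.7613	-2.0669	2
MDC (CCL22)	0.0100	0.0452	-0.0986	-0.9079	-3.4404	1
MIF	0.0362	0.0042	-0.1472	-0.8025	-2.3398	5
MIG (CXCL9)	0.0100	0.1174	-0.0204	-0.6708	-1.6028	0
MIP-1 beta (CCL4)	0.2621	0.0575	-0.0705	-0.2120	-0.3437	1
MIP-1 delta	0.0100	0.0006	-0.0684	-0.8725	-2.9711	3
MIP-3 alpha (CCL20)	0.0100	0.0146	-0.0516	-0.8377	-2.6232	1
NAP-2 (CXCL7)	0.0100	0.0856	-0.0692	-0.8737	-2.9850	0
NT-3	0.3264	0.3826	-0.0320	-0.0894	-0.1351	1
NT-4	0.0807	0.4584	-0.0204	-0.2020	-0.3256	0
OPG (TNFR SF 11)	1.3666	0.6382	0.0410	0.0309	0.0439	1
OPN (SSP1)	0.3109	0.1552	-0.0895	-0.2235	-0.3649	1
OSM	0.4078	0.6803	0.0178	0.0455	0.0642	1
PARC	0.1914	0.8600	-0.0119	-0.0586	-0.0871	0
PDGF-BB	0.0948	0.3120	-0.0265	-0.2187	-0.3561	0
PLGF	0.1465	0.3941	0.0627	0.7481	0.8058	0
RANTES (CCL5)	0.2646	0.6313	0.0288	0.1221	0.1662	1
SCF	0.1688	0.2936	0.0226	0.1546	0.2073	1
SDF-1 alpha (CXCL12)	0.2151	0.9245	-0.0024	-0.0112	-0.0163	0
TARC (CCL17)	0.3281	0.5687	-0.0430	-0.1158	-0.1775	1
TGF beta 1	0.0544	0.0192	-0.0718	-0.5692	-1.2149	1
TGF beta 2	0.6476	0.0122	0.1226	0.2335	0.3028	5
TGF beta 3	0.1224	0.3794	-0.0171	-0.1228	-0.1890	0
TIMP-1	0.6717	0.4984	-0.0302	-0.0430	-0.0634	1
TIMP-2	1.3389	0.1198	-0.0474	-0.0342	-0.0502	1
TNF alpha	0.0100	0.0013	-0.0729	-0.8794	-3.0519	3
TNF beta (TNF SF 1B)	0.0536	0.0996	-0.0943	-0.6377	-1.4649	0
TPO	0.1176	0.0026	0.0337	0.4011	0.4865	4
VEGF-A	0.2579	0.6450	0.0224	0.0952	0.1312	1
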