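index,name,abbreviation,hemisphere,lobe,class
1,Precentral gyrus,PreCG_L,L,central,primary
2,Precentral gyrus,PreCG_R,R,central,primary
3,Superior frontal gyrus,SFGdor_L,L,frontal,association
4,Superior frontal gyrus,SFGdor_R,R,frontal,association
5,Superior orbitofrontal gyrus,ORBsup_L,L,frontal,paralimbic
6,Superior orbitofrontal gyrus,ORBsup_R,R,frontal,paralimbic
7,Middle frontal gyrus,MFG_L,L,frontal,association
8,Middle frontal gyrus,MFG_R,R,frontal,association
9,Middle orbitofrontal gyrus,ORBmid_L,L,frontal,paralimbic
10,Middle orbitofrontal gyrus,ORBmid_R,R,frontal,paralimbic
11,Inferior frontal gyrus (opercular),IFGoperc_L,L,frontal,association
12,Inferior frontal gyrus (opercular),IFGoperc_R,R,frontal,association
13,Inferior frontal gyrus (triangular),IFGtriang_L,L,frontal,association
14,Inferior frontal gyrus (triangular),IFGtriang_R,R,frontal,association
15,Inferior orbitofrontal gyrus,ORBinf_L,L,frontal,paralimbic
16,Inferior orbitofrontal gyrus,ORBinf_R,R,frontal,paralimbic
17,Rolandic operculum,ROL_L,L,central,primary
18,Rolandic operculum,ROL_R,R,central,primary
19,Supplementary motor area,SMA_L,L,frontal,association
20,Supplementary motor area,SMA_R,R,frontal,association
21,Olfactory gyrus,OLF_L,L,frontal,paralimbic
22,Olfactory gyrus,OLF_R,R,frontal,paralimbic
23,Medial frontal gyrus,SFGmed_L,L,frontal,association
24,Medial frontal gyrus,SFGmed_R,R,frontal,association
25,Medial orbitofrontal gyrus,ORBmed_L,L,frontal,paralimbic
26,Medial orbitofrontal gyrus,ORBmed_R,R,frontal,paralimbic
27,Rectus gyrus,REC_L,L,frontal,paralimbic
28,Rectus gyrus,REC_R,R,frontal,paralimbic
29,Insula,INS_L,L,insula,paralimbic
30,Insula,INS_R,R,insula,paralimbic
31,Anterior cingulate gyrus,ACG_L,L,limbic,paralimbic
32,Anterior cingulate gyrus,ACG_R,R,limbic,paralimbic
33,Middle cingulate gyrus,MCG_L,L,limbic,paralimbic
34,Middle cingulate gyrus,MCG_R,R,limbic,paralimbic
35,Posterior cingulate gyrus,PCG_L,L,limbic,paralimbic
36,Posterior cingulate gyrus,PCG_R,R,limbic,paralimbic
37,Hippocampus,HIP_L,L,limbic,paralimbic
38,Hippocampus,HIP_R,R,limbic,paralimbic
39,Parahippocampal gyrus,PHG_L,L,limbic,paralimbic
40,Parahippocampal gyrus,PHG_R,R,limbic,paralimbic
41,Amygdala,AMYG_L,L,limbic,paralimbic
42,Amygdala,AMYG_R,R,limbic,paralimbic
43,Calcarine,CAL_L,L,occipital,primary
44,Calcarine,CAL_R,R,occipital,primary
45,Cuneus,CUN_L,L,occipital,association
46,Cuneus,CUN_R,R,occipital,association
47,Lingual gyrus,LING_L,L,occipital,association
48,Lingual gyrus,LING_R,R,occipital,association
49,Superior occipital gyrus,SOG_L,L,occipital,association
50,Superior occipital gyrus,SOG_R,R,occipital,association
51,Middle occipital gyrus,MOG_L,L,occipital,association
52,Middle occipital gyrus,MOG_R,R,occipital,association
53,Inferior occipital gyrus,IOG_L,L,occipital,association
54,Inferior occipital gyrus,IOG_R,R,occipital,association
55,Fusiform gyrus,FFG_L,L,temporal,association
56,Fusiform gyrus,FFG_R,R,temporal,association
57,Postcentral gyrus,PoCG_L,L,central,primary
58,Postcentral gyrus,PoCG_R,R,central,primary
59,Superior parietal gyrus,SPG_L,L,parietal,association
60,Superior parietal gyrus,SPG_R,R,parietal,association
61,Inferior parietal gyrus,IPL_L,L,parietal,association
62,Inferior parietal gyrus,IPL_R,R,parietal,association
63,Supramarginal gyrus,SMG_L,L,parietal,association
64,Supramarginal gyrus,SMG_R,R,parietal,association
65,Angular gyrus,ANG_L,L,parietal,association
66,Angular gyrus,ANG_R,R,parietal,association
67,Precuneus,PCUN_L,L,parietal,association
68,Precuneus,PCUN_R,R,parietal,association
69,Paracentral lobule,PCL_L,L,central,primary
70,Paracentral lobule,PCL_R,R,central,primary
71,Caudate nucleus,CAU_L,L,subcortical,subcortical
72,Caudate nucleus,CAU_R,R,subcortical,subcortical
73,"Lenticular nucleus, putamen",PUT_L,L,subcortical,subcortical
74,"Lenticular nucleus, putamen",PUT_R,R,subcortical,subcortical
75,"Lenticular nucleus, pallidum",PAL_L,L,subcortical,subcortical
76,"Lenticular nucleus, pallidum",PAL_R,R,subcortical,subcortical
77,Thalamus,THA_L,L,subcortical,subcortical
78,Thalamus,THA_R,R,subcortical,subcortical
79,Heschl gyrus,HES_L,L,temporal,primary
80,Heschl gyrus,HES_R,R,temporal,primary
81,Superior temporal gyrus,STG_L,L,temporal,association
82,Superior temporal gyrus,STG_R,R,temporal,association
83,Temporal pole: superior temporal pole,TPOsup_L,L,temporal,paralimbic
84,Temporal pole: superior temporal pole,TPOsup_R,R,temporal,paralimbic
85,Temporal pole: middle temporal pole,TPOmid_L,L,temporal,paralimbic
86,Temporal pole: middle temporal pole,TPOmid_R,R,temporal,paralimbic
87,Middle temporal gyrus,MTG_L,L,temporal,association
88,Middle temporal gyrus,MTG_R,R,temporal,association
89,Inferior temporal gyrus,ITG_L,L,temporal,association
90,Inferior temporal gyrus,ITG_R,R,temporal,association
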