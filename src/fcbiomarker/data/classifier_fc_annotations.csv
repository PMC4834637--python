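fc_id,lat1,region1,gyral1,ba1,net1,lat2,region2,gyral2,ba2,net2,r_td,r_asd,weight
1,R,Diagonal ramus of the lateral f.,Inferior frontal g.,44,SM,R,Ascending ramus of the lateral f.,Inferior frontal g.,45,CO,0.77,0.71,-0.88
2,R,Subcallosal s.,Middle cingulum,23,DM,R,Calloso-marginal posterior f.,Middle cingulum,23,CO,0.39,0.22,-1.95
3,R,Thalamus,Thalamus,,CO,L,Subcallosal s.,Posterior cingulum,29,DM,0.30,0.10,-2.62
4,R,Amygdala,Amygdala,34,CO,L,Accumbens,Caudate,,CO,0.16,0.05,-2.14
5,R,Rhinal s.,Parahippocampal g.,30,CO,R,Olfactory s.,Rectus,11,DM,0.11,-0.04,-2.11
6,R,Median occipito-temporal lateral s.,Inferior temporal g.,20,CO,L,Anterior inferior frontal s.,Inferior frontal g.,45,FP,0.03,-0.01,-0.98
7,R,Posterior terminal ascending branch of the superior temporal s.,Middle temporal g.,21,DM,R,Internal occipito-temporal lateral s.,Fusiform,37,OC,-0.09,-0.21,-1.26
8,R,Intermediate precentral s.,Middle frontal g.,46,FP,L,Lobe occipital,Middle occipital g.,19,OC,-0.10,-0.19,-1.59
9,L,Polar frontal s.,Superior frontal g.,9,DM,R,Retro central transverse ramus of the lateral f.,Postcentral g.,3,SM,-0.16,-0.29,-1.52
10,R,Caudate,Caudate,,CO,L,Calloso-marginal anterior f.,Anterior cingulum,32,CO,0.17,0.22,0.76
11,R,Olfactory s.,Rectus,11,DM,L,Parieto-occipital f.,Cuneus,18,DM,-0.10,-0.02,1.78
12,L,Pallidum,Pallidum,,CO,R,Superior temporal s.,Superior temporal g.,22,CO,-0.14,0.04,1.90
13,M,Vermis,Vermis,,CB,R,Superior temporal s.,Superior temporal g.,22,CO,-0.18,-0.04,1.85
14,L,Superior parietal s.,Superior parietal g.,7,FP,R,Anterior lateral f.,Inferior frontal g.,47,CO,-0.19,-0.06,0.99
15,R,Inferior precentral s.,Inferior frontal g.,44,SM,R,Parieto-occipital f.,Cuneus,18,OC,-0.24,-0.13,1.00
16,L,Anterior inferior frontal s.,Inferior frontal g.,45,FP,R,Calcarine f.,Calcarine,17,OC,-0.24,-0.16,1.74
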