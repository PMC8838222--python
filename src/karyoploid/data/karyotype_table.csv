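species,individuals,plates,two_n,cl_um,q_um,p_um,tf_pct,s_pct,ask_pct,syi_pct,r,ci,kf
A. assadabadensis,7,11,16,3.4,1.44,1.95,42,74,57,74,1.38,0.42,1M + 6m + 1sm
A. chrysostachys,3,5,16,1.47,0.66,0.81,45,61,55,81,1.26,0.43,2M + 5m + 1sm
A. hymenostegis,10,14,16,2.08,0.89,1.19,43,69,57,75,1.34,0.42,8m
A. lagopoides,5,9,48,1.74,0.72,1.02,41,61,58,70,1.44,0.41,1M + 21m + 2sm
A. melanostictus,9,8,32,2.27,0.93,1.34,41,60,59,69,1.44,0.42,13m + 3sm
A. nervistipulus,6,8,16,2.09,0.82,1.26,39,69,60,65,1.57,0.41,5m + 3sm
A. paralurges,9,11,16,2.06,0.86,1.2,41,66,58,71,1.43,0.39,6m + 2sm
A. pediculariformis,6,11,16,2.12,0.96,1.15,45,71,54,83,1.23,0.45,2M + 5m + 1sm
A. pereshkhoranicus,6,9,16,2.32,0.88,1.43,38,80,62,61,1.65,0.41,6m + 2sm
A. qorvehensis,8,9,32,1.79,0.77,1.02,43,52,57,75,1.34,0.41,2M + 12m + 2sm
A. remotispicatus,10,8,16,2.26,0.95,1.3,42,47,58,73,1.39,0.43,1M + 6m + 1sm
A. rubrostriatus,5,9,48,2.01,0.85,1.16,42,57,57,73,1.4,0.44,2M + 18m + 4sm
A. seidabadensis,10,8,16,2.31,0.94,1.36,41,63,59,69,1.46,0.38,1M + 5m + 2sm
A. sohrevardianus,7,10,32,1.91,0.79,1.12,41,50,58,71,1.40,0.36,15m + 1sm
A. subrecognitus,10,7,16,3.5,1.41,2.8,40,53,59,68,1.48,0.38,2M + 3m + 3sm
A. tabrizianus,5,7,16,2.75,0.99,1.76,36,59,63,56,1.77,0.38,3m + 5sm
A. tricholobus,8,7,32,2.16,0.82,1.33,38,58,62,61,1.66,0.43,1M + 8m + 7sm
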