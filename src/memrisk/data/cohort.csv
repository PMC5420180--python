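patient_id,sex,age_onset,duration,side,dominant_hemisphere,mri_positive,cd_list_baseline,cd_delayed_baseline,rcft_baseline,cd_list_change,cd_delayed_change,rcft_change,li_broca_verbal,li_mtl_verbal,li_mtl_visuospatial,resected_volume,remaining_hc_volume,seizure_free,intertest_interval
1,M,28,13,R,left,True,-0.5,0.3,-0.5,0.6,0.1,-1.7,0.75,0.86,0.15,28,,False,5.5
2,F,17,18,R,left,True,0.3,0.5,-2.2,0.3,-0.5,0.6,0.32,0.6,0.62,25,0.2,False,18
3,M,47,7,R,left,False,0.5,0.7,0.7,-0.8,-2.1,0.0,0.75,0.25,0.14,39,0.2,True,8
4,F,34,5,R,left,False,1.0,0.6,-1.3,-1.6,0.0,0.5,0.056,-0.12,0.39,24,0.3,True,7.5
5,F,34,4,R,left,False,-0.5,-0.2,-2.3,-0.5,-1.1,-0.7,-0.036,-0.26,0.15,47,0.0,True,10
6,F,8,19,R,left,True,-1.6,-2.5,-2.6,-0.4,0.8,-0.4,-0.15,-0.037,0.66,22,1.6,True,7
7,M,15,32,L,left,True,-0.7,-1.3,0.5,1.1,-0.7,0.7,0.3,-0.41,0.4,8,1.9,False,4
8,M,19,4,L,left,True,-1.4,0.1,-1.9,-1.2,-0.1,1.2,0.33,-0.58,0.52,25,0.1,True,20
9,F,1,31,L,left,True,0.1,-2.1,-1.1,-1.5,-0.9,0.3,0.55,-0.66,0.33,22,0.1,True,12
10,F,19,12,L,left,True,-3.3,-2.7,,-1.7,-1.8,,0.55,-0.5,0.53,19,0.2,True,6.5
11,M,25,5,L,left,True,0.8,-4.5,-1.6,-2.5,3.1,-0.4,0.74,-0.27,0.003,27,2.4,True,24
12,F,10,20,L,left,True,-0.2,-0.1,0.0,-0.4,0.0,1.0,0.51,0.039,0.22,31,0.0,True,12
13,F,13,11,L,left,False,-0.8,-0.8,-1.2,-2.6,-0.5,-0.4,0.54,0.042,-0.46,18,0.5,False,19
14,F,32,28,L,left,True,-2.2,-0.5,-1.3,0.9,-2.1,-1.7,-0.48,-0.74,-0.36,17,0.3,True,11
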