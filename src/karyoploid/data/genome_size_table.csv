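species,individual,genus,section,counted,two_n,standard_name,mean_standard,mean_sample,cv_standard_pct,cv_sample_pct,two_c_pg
A. assadabadensis,1,Astragalus,Hymenostegis,True,16,Maize,103.79,41.55,2.89,7.39,2.17
A. atrokurdicus,1,Astragalus,Hymenostegis,False,,Maize,100.46,82.66,4.11,3.93,4.47
A. austrotaromensis,1,Astragalus,Hymenostegis,False,,Maize,97.78,44.89,5.13,13.66,2.49
A. austrotaromensis,2,Astragalus,Hymenostegis,False,,Maize,98.71,44.07,6,9.29,2.42
A. bashmaghensis,1,Astragalus,Hymenostegis,False,,Maize,99.82,82.07,2.18,5.8,4.46
A. bashmaghensis,2,Astragalus,Hymenostegis,False,,Maize,99.76,86.54,2.32,6.3,4.71
A. callistachys,1,Astragalus,Microphysa,False,,Maize,105.69,89.41,2.86,4.22,4.59
A. campylanthus,1,Astragalus,Campylanthus,False,,Maize,107.48,44.4,4.62,15.56,2.24
A. chehreganii,1,Astragalus,Hymenostegis,False,,Maize,100.12,85,2.86,4.57,4.61
A. chrysostachys,1,Astragalus,Hymenostegis,True,16,Maize,96.88,40.73,2.12,5.38,2.28
A. chrysostachys,2,Astragalus,Hymenostegis,False,,Maize,95.07,39.75,2.25,3.64,2.27
A. chrysostachys,3,Astragalus,Hymenostegis,False,,Maize,102.08,42.77,2.63,4.62,2.28
A. chrysostachys,4,Astragalus,Hymenostegis,False,,Maize,92.23,40.35,9.1,6.22,2.38
A. commixtus,1,Astragalus,Ankylotus,False,,Maize,71.75,90.1,5.66,6.54,6.82
A. commixtus,2,Astragalus,Ankylotus,False,,Maize,90.1,71.75,6.54,5.66,4.32
A. expetitus,1,Astragalus,Hymenostegis,False,,Maize,107.56,91.85,2.59,4.58,4.64
A. glumaceus,1,Astragalus,Hymenostegis,False,,Maize,94.97,45.5,3.2,7.18,2.60
A. glumaceus,2,Astragalus,Hymenostegis,False,,Maize,92.6,43.69,8.5,9.32,2.56
A. hirticalyx,1,Astragalus,Hymenostegis,False,,Maize,98.46,41.49,3.01,14,2.29
A. hirticalyx,2,Astragalus,Hymenostegis,False,,Maize,99.01,39.38,4.06,10.32,2.16
A. hymenocystis,1,Astragalus,Hymenostegis,False,,Maize,98.2,36.28,4.37,9.4,2.01
A. hymenostegis,1,Astragalus,Hymenostegis,True,16,Maize,97.38,39.64,2.81,8.86,2.21
A. hymenostegis,2,Astragalus,Hymenostegis,False,,Maize,100.09,43.8,2.91,7.73,2.38
A. karl-heinzii,1,Astragalus,Hymenostegis,False,,Maize,98.62,42.52,2.63,5.39,2.34
A. karl-heinzii,2,Astragalus,Hymenostegis,False,,Maize,98.22,42.92,3.09,12.49,2.37
A. lagopoides,1,Astragalus,Hymenostegis,True,48,Maize,101.34,117.52,2.9,4.73,6.30
A. marivanensis,1,Astragalus,Hymenostegis,False,,Maize,95.93,37.21,2.71,5.35,2.11
A. melanostictus,1,Astragalus,Hymenostegis,True,32,Maize,96.98,27.46,2.31,6.23,1.54
A. melanostictus,2,Astragalus,Hymenostegis,False,,Maize,94.33,38.41,2.74,6.74,2.21
A. murinus,1,Astragalus,Anthylloidei,False,,Maize,109.86,51.54,4.48,8.13,2.55
A. nervistipulus,1,Astragalus,Hymenostegis,True,16,Maize,101.86,44.28,4.09,9.96,2.36
A. paralurges,1,Astragalus,Hymenostegis,True,16,Maize,101.33,40.97,2.89,7.52,2.20
A. paralurges,2,Astragalus,Hymenostegis,False,,Maize,103,41.03,2.93,8.64,2.16
A. pediculariformis,1,Astragalus,Hymenostegis,True,16,Maize,99.17,42.6,2.19,15.63,2.33
A. pediculariformis,2,Astragalus,Hymenostegis,False,,Maize,101.82,42.4,2.41,5.63,2.26
A. pereshkhoranicus,1,Astragalus,Hymenostegis,True,16,Maize,99,36.63,3.37,13.81,2.01
A. pseudopersicus,1,Astragalus,Hymenostegis,False,,Maize,108.18,43.46,2.35,15.41,2.18
A. pseudopersicus,2,Astragalus,Hymenostegis,False,,Maize,108.56,43.93,2.54,6.95,2.20
A. qorvehensis,1,Astragalus,Hymenostegis,True,32,,,,,,
A. remotispicatus,1,Astragalus,Hymenostegis,True,16,Maize,101.27,45.85,2.51,10.75,2.46
A. rubrostriatus,1,Astragalus,Hymenostegis,True,48,Maize,104.93,132.77,4.12,5.63,6.87
A. rubrostriatus,2,Astragalus,Hymenostegis,False,,Maize,102.25,134.82,5.92,6.4,7.16
A. salavatabadensis,1,Astragalus,Hymenostegis,False,,Maize,97.82,42.51,2.58,14.68,2.36
A. salavatabadensis,2,Astragalus,Hymenostegis,False,,Maize,98.35,41.68,2.67,8.35,2.30
A. seidabadensis,1,Astragalus,Hymenostegis,True,16,Maize,107.19,45.89,3.17,10.13,2.32
A. seidabadensis,2,Astragalus,Hymenostegis,False,,Maize,100.86,43.84,3.2,12.04,2.36
A. seidabadensis,3,Astragalus,Hymenostegis,False,,Maize,99.1,40.61,6.14,7.77,2.23
A. sohrevardianus,1,Astragalus,Hymenostegis,True,32,,,,,,
A. sosnowskyi,1,Astragalus,Hymenostegis,False,,Maize,101.12,87.27,2.45,5.66,4.69
A. sosnowskyi,2,Astragalus,Hymenostegis,False,,Maize,97.17,80.67,2.96,4.77,4.51
A. submitis,1,Astragalus,Hymenostegis/Anthylloidei,False,,Maize,96.81,84.59,2.17,3.91,4.74
A. subrecognitus,1,Astragalus,Hymenostegis,True,16,Maize,103.36,49.07,2.36,7.48,2.58
A. subrecognitus,2,Astragalus,Hymenostegis,False,,Maize,100.5,45.96,2.54,7.77,2.48
A. supervisus,1,Astragalus,Incani,False,,Maize,96.85,29.51,3.05,5.71,1.65
A. tabrizianus,1,Astragalus,Hymenostegis,True,16,Maize,99.65,40.18,3.5,11.97,2.19
A. tortuosus,1,Astragalus,Anthylloidei,False,,Maize,100.76,39.76,2.72,5.77,2.14
A. tricholobus,1,Astragalus,Hymenostegis,True,32,Maize,100.12,83.07,2.05,3.69,4.51
A. tricholobus,2,Astragalus,Hymenostegis,False,,Maize,106.19,91.9,2.18,6.95,4.70
A. tricholobus,3,Astragalus,Hymenostegis,False,,Maize,99.62,81.91,2.31,5.73,4.46
A. tricholobus,4,Astragalus,Hymenostegis,False,,Maize,105.11,89.07,2.48,4.3,4.60
A. uraniolimneus,1,Astragalus,Hymenostegis,False,,Maize,97.09,79.09,2.42,3.29,4.42
A. vernaculus,1,Astragalus,Hymenostegis,False,,Maize,103.65,43.36,2.84,13.59,2.27
A. vernaculus,2,Astragalus,Hymenostegis,False,,Maize,96.61,42.38,3.09,6.58,2.38
A. zohrabi,1,Astragalus,Hymenostegis,False,,Maize,100.14,38.14,3.4,7.73,2.07
O. chrysocarpa,1,Oxytropis,,False,,Maize,106.11,59.34,3.1,5.99,3.04
O. kotschyana,1,Oxytropis,,False,,Maize,105.35,55.09,3.8,5.49,2.84
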