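# SYNTHETIC modern-style active-marrow and bone-endosteum site fractions
# for the 25-site skeletal reconstruction; NOT measured reference data.
# Fractions are normalized to sum to 1 per (tissue, age).
site,tissue,infant,child,adult
cranium,active_marrow,0.064297800338,0.070842654735,0.076000000000
facial_bones,active_marrow,0.006768189509,0.007457121551,0.008000000000
teeth,active_marrow,0.000000000000,0.000000000000,0.000000000000
mandible,active_marrow,0.006768189509,0.007457121551,0.008000000000
hyoid,active_marrow,0.000423011844,0.000466070097,0.000500000000
cervical_spine,active_marrow,0.032994923858,0.036353467562,0.039000000000
thoracic_spine,active_marrow,0.136209813875,0.150074571216,0.161000000000
lumbar_spine,active_marrow,0.104060913706,0.114653243848,0.123000000000
sacrum,active_marrow,0.083756345178,0.092281879195,0.099000000000
coccyx,active_marrow,0.000423011844,0.000466070097,0.000500000000
sternum,active_marrow,0.026226734349,0.028896346010,0.031000000000
ribs_upper,active_marrow,0.067681895093,0.074571215511,0.080000000000
ribs_lower,active_marrow,0.068527918782,0.075503355705,0.081000000000
clavicles,active_marrow,0.006768189509,0.007457121551,0.008000000000
scapulae,active_marrow,0.023688663283,0.026099925429,0.028000000000
pelvis,active_marrow,0.148054145516,0.163124533930,0.175000000000
patellae,active_marrow,0.005922165821,0.003169276659,0.001000000000
arm_bone_upper,active_marrow,0.058375634518,0.038590604027,0.023000000000
arm_bone_middle,active_marrow,0.007614213198,0.005033557047,0.003000000000
arm_bone_lower,active_marrow,0.005922165821,0.003169276659,0.001000000000
leg_bone_upper,active_marrow,0.111675126904,0.073825503356,0.044000000000
leg_bone_middle,active_marrow,0.015228426396,0.010067114094,0.006000000000
leg_bone_lower,active_marrow,0.006768189509,0.004101416853,0.002000000000
hands,active_marrow,0.005922165821,0.003169276659,0.001000000000
feet,active_marrow,0.005922165821,0.003169276659,0.001000000000
cranium,endosteum,0.090000000000,0.090000000000,0.090000000000
facial_bones,endosteum,0.020000000000,0.020000000000,0.020000000000
teeth,endosteum,0.003000000000,0.003000000000,0.003000000000
mandible,endosteum,0.015000000000,0.015000000000,0.015000000000
hyoid,endosteum,0.002000000000,0.002000000000,0.002000000000
cervical_spine,endosteum,0.030000000000,0.030000000000,0.030000000000
thoracic_spine,endosteum,0.070000000000,0.070000000000,0.070000000000
lumbar_spine,endosteum,0.060000000000,0.060000000000,0.060000000000
sacrum,endosteum,0.045000000000,0.045000000000,0.045000000000
coccyx,endosteum,0.003000000000,0.003000000000,0.003000000000
sternum,endosteum,0.015000000000,0.015000000000,0.015000000000
ribs_upper,endosteum,0.060000000000,0.060000000000,0.060000000000
ribs_lower,endosteum,0.060000000000,0.060000000000,0.060000000000
clavicles,endosteum,0.015000000000,0.015000000000,0.015000000000
scapulae,endosteum,0.040000000000,0.040000000000,0.040000000000
pelvis,endosteum,0.120000000000,0.120000000000,0.120000000000
patellae,endosteum,0.007000000000,0.007000000000,0.007000000000
arm_bone_upper,endosteum,0.040000000000,0.040000000000,0.040000000000
arm_bone_middle,endosteum,0.030000000000,0.030000000000,0.030000000000
arm_bone_lower,endosteum,0.040000000000,0.040000000000,0.040000000000
leg_bone_upper,endosteum,0.060000000000,0.060000000000,0.060000000000
leg_bone_middle,endosteum,0.050000000000,0.050000000000,0.050000000000
leg_bone_lower,endosteum,0.060000000000,0.060000000000,0.060000000000
hands,endosteum,0.030000000000,0.030000000000,0.030000000000
feet,endosteum,0.035000000000,0.035000000000,0.035000000000
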