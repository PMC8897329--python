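# SYNTHETIC ds86-style active-marrow and bone-endosteum site fractions
# for the 25-site skeletal reconstruction; NOT measured reference data.
# Fractions are normalized to sum to 1 per (tissue, age).
site,tissue,infant,child,adult
cranium,active_marrow,0.056379821958,0.066713483146,0.076000000000
facial_bones,active_marrow,0.005934718101,0.007022471910,0.008000000000
teeth,active_marrow,0.000000000000,0.000000000000,0.000000000000
mandible,active_marrow,0.005934718101,0.007022471910,0.008000000000
hyoid,active_marrow,0.000370919881,0.000438904494,0.000500000000
cervical_spine,active_marrow,0.028931750742,0.034234550562,0.039000000000
thoracic_spine,active_marrow,0.100890207715,0.119382022472,0.136000000000
lumbar_spine,active_marrow,0.076409495549,0.090414325843,0.103000000000
sacrum,active_marrow,0.062314540059,0.073735955056,0.084000000000
coccyx,active_marrow,0.000370919881,0.000438904494,0.000500000000
sternum,active_marrow,0.022997032641,0.027212078652,0.031000000000
ribs_upper,active_marrow,0.059347181009,0.070224719101,0.080000000000
ribs_lower,active_marrow,0.060089020772,0.071102528090,0.081000000000
clavicles,active_marrow,0.005934718101,0.007022471910,0.008000000000
scapulae,active_marrow,0.020771513353,0.024578651685,0.028000000000
pelvis,active_marrow,0.107566765579,0.127282303371,0.145000000000
patellae,active_marrow,0.005192878338,0.002984550562,0.001000000000
arm_bone_upper,active_marrow,0.084569732938,0.060042134831,0.038000000000
arm_bone_middle,active_marrow,0.026706231454,0.018960674157,0.012000000000
arm_bone_lower,active_marrow,0.013353115727,0.009480337079,0.006000000000
leg_bone_upper,active_marrow,0.164688427300,0.116924157303,0.074000000000
leg_bone_middle,active_marrow,0.048961424332,0.034761235955,0.022000000000
leg_bone_lower,active_marrow,0.022255192878,0.015800561798,0.010000000000
hands,active_marrow,0.008902077151,0.006320224719,0.004000000000
feet,active_marrow,0.011127596439,0.007900280899,0.005000000000
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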