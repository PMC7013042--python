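abbreviation,gyrus,lobe,mean_degree
Hipp_L_2_1,Hippocampus,Subcortical nuclei,19.351
Hipp_R_2_2,Hippocampus,Subcortical nuclei,17.907
BG_R_6_5,Basal ganglia,Subcortical nuclei,16.835
Hipp_L_2_2,Hippocampus,Subcortical nuclei,16.464
Hipp_R_2_1,Hippocampus,Subcortical nuclei,15.948
FuG_L_3_3,Fusiform gyrus,Temporal lobe,15.835
BG_L_6_5,Basal ganglia,Subcortical nuclei,15.784
FuG_L_3_1,Fusiform gyrus,Temporal lobe,14.557
FuG_R_3_1,Fusiform gyrus,Temporal lobe,14.474
OrG_L_6_5,Orbital gyrus,Frontal lobe,14.309
BG_R_6_3,Basal ganglia,Subcortical nuclei,14.134
FuG_R_3_3,Fusiform gyrus,Temporal lobe,14.134
BG_R_6_6,Basal ganglia,Subcortical nuclei,13.361
BG_L_6_6,Basal ganglia,Subcortical nuclei,13.34
OrG_R_6_3,Orbital gyrus,Frontal lobe,12.784
FuG_L_3_2,Fusiform gyrus,Temporal lobe,12.639
MVOcC_L_5_5,Medioventral occipital cortex,Occipital lobe,12.619
MVOcC_R_5_5,Medioventral occipital cortex,Occipital lobe,12.598
PCun_R_4_3,Precuneus,Parietal lobe,12.289
OrG_R_6_5,Orbital gyrus,Frontal lobe,12.206
OrG_L_6_3,Orbital gyrus,Frontal lobe,12.103
PCun_L_4_3,Precuneus,Parietal lobe,11.948
BG_L_6_3,Basal ganglia,Subcortical nuclei,11.835
Tha_L_8_7,Thalamus,Subcortical nuclei,11.753
Tha_R_8_7,Thalamus,Subcortical nuclei,11.68
BG_L_6_4,Basal ganglia,Subcortical nuclei,11.619
BG_R_6_2,Basal ganglia,Subcortical nuclei,11.247
FuG_R_3_2,Fusiform gyrus,Temporal lobe,11.165
BG_L_6_2,Basal ganglia,Subcortical nuclei,11.093
IPL_R_6_6,Inferior parietal lobule,Parietal lobe,10.979
INS_L_6_6,Insular gyrus,Insular lobe,10.856
BG_R_6_4,Basal ganglia,Subcortical nuclei,10.825
PrG_R_6_6,Precentral gyrus,Frontal lobe,10.784
BG_L_6_1,Basal ganglia,Subcortical nuclei,10.577
STG_R_6_3,Superior temporal gyrus,Temporal lobe,10.577
IPL_L_6_1,Inferior parietal lobule,Parietal lobe,10.392
Tha_L_8_4,Thalamus,Subcortical nuclei,10.361
MTG_R_4_4,Middle temporal gyrus,Temporal lobe,10.351
MTG_L_4_4,Middle temporal gyrus,Temporal lobe,10.34
MVOcC_R_5_4,Medioventral occipital cortex,Occipital lobe,10.32
IFG_R_6_5,Inferior frontal gyrus,Frontal lobe,10.278
STG_L_6_1,Superior temporal gyrus,Temporal lobe,10.144
MVOcC_L_5_2,Medioventral occipital cortex,Occipital lobe,10.034
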