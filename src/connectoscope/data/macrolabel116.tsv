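label	hemisphere
Precentral_L	L
Precentral_R	R
Frontal_Sup_L	L
Frontal_Sup_R	R
Frontal_Sup_Orb_L	L
Frontal_Sup_Orb_R	R
Frontal_Mid_L	L
Frontal_Mid_R	R
Frontal_Mid_Orb_L	L
Frontal_Mid_Orb_R	R
Frontal_Inf_Oper_L	L
Frontal_Inf_Oper_R	R
Frontal_Inf_Tri_L	L
Frontal_Inf_Tri_R	R
Frontal_Inf_Orb_L	L
Frontal_Inf_Orb_R	R
Rolandic_Oper_L	L
Rolandic_Oper_R	R
Supp_Motor_Area_L	L
Supp_Motor_Area_R	R
Olfactory_L	L
Olfactory_R	R
Frontal_Sup_Medial_L	L
Frontal_Sup_Medial_R	R
Frontal_Med_Orb_L	L
Frontal_Med_Orb_R	R
Rectus_L	L
Rectus_R	R
Insula_L	L
Insula_R	R
Cingulum_Ant_L	L
Cingulum_Ant_R	R
Cingulum_Mid_L	L
Cingulum_Mid_R	R
Cingulum_Post_L	L
Cingulum_Post_R	R
Hippocampus_L	L
Hippocampus_R	R
ParaHippocampal_L	L
ParaHippocampal_R	R
Amygdala_L	L
Amygdala_R	R
Calcarine_L	L
Calcarine_R	R
Cuneus_L	L
Cuneus_R	R
Lingual_L	L
Lingual_R	R
Occipital_Sup_L	L
Occipital_Sup_R	R
Occipital_Mid_L	L
Occipital_Mid_R	R
Occipital_Inf_L	L
Occipital_Inf_R	R
Fusiform_L	L
Fusiform_R	R
Postcentral_L	L
Postcentral_R	R
Parietal_Sup_L	L
Parietal_Sup_R	R
Parietal_Inf_L	L
Parietal_Inf_R	R
SupraMarginal_L	L
SupraMarginal_R	R
Angular_L	L
Angular_R	R
Precuneus_L	L
Precuneus_R	R
Paracentral_Lobule_L	L
Paracentral_Lobule_R	R
Caudate_L	L
Caudate_R	R
Putamen_L	L
Putamen_R	R
Pallidum_L	L
Pallidum_R	R
Thalamus_L	L
Thalamus_R	R
Heschl_L	L
Heschl_R	R
Temporal_Sup_L	L
Temporal_Sup_R	R
Temporal_Pole_Sup_L	L
Temporal_Pole_Sup_R	R
Temporal_Mid_L	L
Temporal_Mid_R	R
Temporal_Pole_Mid_L	L
Temporal_Pole_Mid_R	R
Temporal_Inf_L	L
Temporal_Inf_R	R
Cerebelum_Crus1_L	L
Cerebelum_Crus1_R	R
Cerebelum_Crus2_L	L
Cerebelum_Crus2_R	R
Cerebelum_3_L	L
Cerebelum_3_R	R
Cerebelum_4_5_L	L
Cerebelum_4_5_R	R
Cerebelum_6_L	L
Cerebelum_6_R	R
Cerebelum_7b_L	L
Cerebelum_7b_R	R
Cerebelum_8_L	L
Cerebelum_8_R	R
Cerebelum_9_L	L
Cerebelum_9_R	R
Cerebelum_10_L	L
Cerebelum_10_R	R
Vermis_1_2	M
Vermis_3	M
Vermis_4_5	M
Vermis_6	M
Vermis_7	M
Vermis_8	M
Vermis_9	M
Vermis_10	M
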