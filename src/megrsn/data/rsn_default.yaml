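# 78-ROI cortical atlas registry (automated anatomical labelling
# parcellation with subcortical structures removed) and the four
# default resting-state networks.  Memberships are a documented
# literature-based approximation and are data, not code: edit or
# version this file to change network definitions.

registry:
  - Precentral_L
  - Precentral_R
  - Frontal_Sup_L
  - Frontal_Sup_R
  - Frontal_Sup_Orb_L
  - Frontal_Sup_Orb_R
  - Frontal_Mid_L
  - Frontal_Mid_R
  - Frontal_Mid_Orb_L
  - Frontal_Mid_Orb_R
  - Frontal_Inf_Oper_L
  - Frontal_Inf_Oper_R
  - Frontal_Inf_Tri_L
  - Frontal_Inf_Tri_R
  - Frontal_Inf_Orb_L
  - Frontal_Inf_Orb_R
  - Rolandic_Oper_L
  - Rolandic_Oper_R
  - Supp_Motor_Area_L
  - Supp_Motor_Area_R
  - Olfactory_L
  - Olfactory_R
  - Frontal_Sup_Medial_L
  - Frontal_Sup_Medial_R
  - Frontal_Med_Orb_L
  - Frontal_Med_Orb_R
  - Rectus_L
  - Rectus_R
  - Insula_L
  - Insula_R
  - Cingulum_Ant_L
  - Cingulum_Ant_R
  - Cingulum_Mid_L
  - Cingulum_Mid_R
  - Cingulum_Post_L
  - Cingulum_Post_R
  - ParaHippocampal_L
  - ParaHippocampal_R
  - Calcarine_L
  - Calcarine_R
  - Cuneus_L
  - Cuneus_R
  - Lingual_L
  - Lingual_R
  - Occipital_Sup_L
  - Occipital_Sup_R
  - Occipital_Mid_L
  - Occipital_Mid_R
  - Occipital_Inf_L
  - Occipital_Inf_R
  - Fusiform_L
  - Fusiform_R
  - Postcentral_L
  - Postcentral_R
  - Parietal_Sup_L
  - Parietal_Sup_R
  - Parietal_Inf_L
  - Parietal_Inf_R
  - SupraMarginal_L
  - SupraMarginal_R
  - Angular_L
  - Angular_R
  - Precuneus_L
  - Precuneus_R
  - Paracentral_Lobule_L
  - Paracentral_Lobule_R
  - Heschl_L
  - Heschl_R
  - Temporal_Sup_L
  - Temporal_Sup_R
  - Temporal_Pole_Sup_L
  - Temporal_Pole_Sup_R
  - Temporal_Mid_L
  - Temporal_Mid_R
  - Temporal_Pole_Mid_L
  - Temporal_Pole_Mid_R
  - Temporal_Inf_L
  - Temporal_Inf_R

networks:
  DMN:
    members:
      - Frontal_Sup_Medial_L
      - Frontal_Sup_Medial_R
      - Frontal_Med_Orb_L
      - Frontal_Med_Orb_R
      - Cingulum_Post_L
      - Cingulum_Post_R
      - Precuneus_L
      - Precuneus_R
      - Angular_L
      - Angular_R
      - ParaHippocampal_L
      - ParaHippocampal_R
  FPN_left:
    hemisphere: L
    members:
      - Frontal_Sup_L
      - Frontal_Mid_L
      - Frontal_Inf_Tri_L
      - Parietal_Sup_L
      - Parietal_Inf_L
      - SupraMarginal_L
      - Angular_L
  FPN_right:
    hemisphere: R
    members:
      - Frontal_Sup_R
      - Frontal_Mid_R
      - Frontal_Inf_Tri_R
      - Parietal_Sup_R
      - Parietal_Inf_R
      - SupraMarginal_R
      - Angular_R
  ECN:
    members:
      - Frontal_Sup_L
      - Frontal_Sup_R
      - Frontal_Mid_L
      - Frontal_Mid_R
      - Cingulum_Ant_L
      - Cingulum_Ant_R
      - Cingulum_Mid_L
      - Cingulum_Mid_R
      - Supp_Motor_Area_L
      - Supp_Motor_Area_R
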