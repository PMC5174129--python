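sample_id,genotype,condition,timepoint,replicate,rewatered
tolerant_D_A_r1,tolerant,drought,A,1,False
tolerant_D_A_r2,tolerant,drought,A,2,False
tolerant_D_B_r1,tolerant,drought,B,1,False
tolerant_D_B_r2,tolerant,drought,B,2,False
tolerant_D_C_r1,tolerant,drought,C,1,False
tolerant_D_C_r2,tolerant,drought,C,2,False
tolerant_D_D_r1,tolerant,drought,D,1,False
tolerant_D_D_r2,tolerant,drought,D,2,False
tolerant_D_E_r1,tolerant,drought,E,1,False
tolerant_D_E_r2,tolerant,drought,E,2,False
tolerant_D_F_r1,tolerant,drought,F,1,True
tolerant_D_F_r2,tolerant,drought,F,2,True
tolerant_W_A_r1,tolerant,well_watered,A,1,False
tolerant_W_A_r2,tolerant,well_watered,A,2,False
tolerant_W_B_r1,tolerant,well_watered,B,1,False
tolerant_W_B_r2,tolerant,well_watered,B,2,False
tolerant_W_C_r1,tolerant,well_watered,C,1,False
tolerant_W_C_r2,tolerant,well_watered,C,2,False
tolerant_W_D_r1,tolerant,well_watered,D,1,False
tolerant_W_D_r2,tolerant,well_watered,D,2,False
tolerant_W_E_r1,tolerant,well_watered,E,1,False
tolerant_W_E_r2,tolerant,well_watered,E,2,False
tolerant_W_F_r1,tolerant,well_watered,F,1,True
tolerant_W_F_r2,tolerant,well_watered,F,2,True
susceptible_D_A_r1,susceptible,drought,A,1,False
susceptible_D_A_r2,susceptible,drought,A,2,False
susceptible_D_B_r1,susceptible,drought,B,1,False
susceptible_D_B_r2,susceptible,drought,B,2,False
susceptible_D_C_r1,susceptible,drought,C,1,False
susceptible_D_C_r2,susceptible,drought,C,2,False
susceptible_D_D_r1,susceptible,drought,D,1,False
susceptible_D_D_r2,susceptible,drought,D,2,False
susceptible_D_E_r1,susceptible,drought,E,1,False
susceptible_D_E_r2,susceptible,drought,E,2,False
susceptible_D_F_r1,susceptible,drought,F,1,True
susceptible_D_F_r2,susceptible,drought,F,2,True
susceptible_W_A_r1,susceptible,well_watered,A,1,False
susceptible_W_A_r2,susceptible,well_watered,A,2,False
susceptible_W_B_r1,susceptible,well_watered,B,1,False
susceptible_W_B_r2,susceptible,well_watered,B,2,False
susceptible_W_C_r1,susceptible,well_watered,C,1,False
susceptible_W_C_r2,susceptible,well_watered,C,2,False
susceptible_W_D_r1,susceptible,well_watered,D,1,False
susceptible_W_D_r2,susceptible,well_watered,D,2,False
susceptible_W_E_r1,susceptible,well_watered,E,1,False
susceptible_W_E_r2,susceptible,well_watered,E,2,False
susceptible_W_F_r1,susceptible,well_watered,F,1,True
susceptible_W_F_r2,susceptible,well_watered,F,2,True
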