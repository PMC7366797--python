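run_id,role,source_quality,mean_energy_keV,geometry,zenith_angle_deg,dose_rate_mGy_h,duration_s,n_rotations,reference_distance_m
CAL-662-AP,calibration,Cs-137,662,AP,,10.5,720,,3.5
N150-AP,phantom,N-150,119,AP,,27.6,315,,3.38
N150-ROT030,phantom,N-150,119,ROT,30,25.7,180,4,3.5
N150-ROT060,phantom,N-150,119,ROT,60,25.7,180,4,3.5
N150-ROT090,phantom,N-150,119,ROT,90,25.7,180,4,3.5
N150-ROT120,phantom,N-150,119,ROT,120,25.7,180,4,3.5
N150-ROT150,phantom,N-150,119,ROT,150,25.7,180,4,3.5
N250-AP,phantom,N-250,207,AP,,7.88,990,,3.38
N250-ROT030,phantom,N-250,207,ROT,30,7.33,445,11,3.5
N250-ROT060,phantom,N-250,207,ROT,60,7.33,445,11,3.5
N250-ROT090,phantom,N-250,207,ROT,90,7.33,445,11,3.5
N250-ROT120,phantom,N-250,207,ROT,120,7.33,445,11,3.5
N250-ROT150,phantom,N-250,207,ROT,150,7.33,445,11,3.5
CS137-AP,phantom,Cs-137,662,AP,,11.3,720,,3.38
CS137-ROT030,phantom,Cs-137,662,ROT,30,10.5,360,8,3.5
CS137-ROT060,phantom,Cs-137,662,ROT,60,10.5,360,8,3.5
CS137-ROT090,phantom,Cs-137,662,ROT,90,10.5,360,8,3.5
CS137-ROT120,phantom,Cs-137,662,ROT,120,10.5,360,8,3.5
CS137-ROT150,phantom,Cs-137,662,ROT,150,10.5,360,8,3.5
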