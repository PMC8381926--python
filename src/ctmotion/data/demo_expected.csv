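pair_id,mode,frame,tx_mm,ty_mm,tz_mm,rx_deg,ry_deg,rz_deg,com_x_mm,com_y_mm,com_z_mm,bone_mean_error_mm,bone_condition_number,bone_n_points,bone_converged,bone_iterations,implant_mean_error_mm,implant_condition_number,implant_n_points,implant_converged,implant_iterations,gimbal_warning
demo0,beads,dicom,-0.001209,0.001006,-0.002280,-0.054345,0.056739,-0.043137,23.759527,23.697240,27.619580,0.016957,3.893507,6,True,1,0.035165,1.937353,18352,True,3,False
demo1,beads,dicom,0.499764,0.002342,-0.007582,0.068678,-0.032692,1.158018,23.783806,23.710345,27.610476,0.029333,3.305205,6,True,1,0.047810,1.931476,18342,True,4,False
demo2,beads,dicom,0.106089,-0.297812,0.398535,0.015397,1.504184,0.138277,23.758426,23.694033,27.616393,0.015421,5.800736,6,True,1,0.035982,1.937517,18360,True,3,False
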