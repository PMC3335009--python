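indicator,model,D_theta,p_d,DIC,var_str,var_str_lo,var_str_hi,var_unstr,var_unstr_lo,var_unstr_hi,rho
early,VCM,4203.80,216.34,4420.14,2.26,0.76,4.62,0.56,0.02,1.02,0.80
early,REM,4201.45,222.74,4424.19,3.96,1.92,6.29,0.42,0.003,1.03,0.90
advanced,VCM,4200.53,210.89,4411.42,3.18,1.25,5.64,0.43,0.004,0.94,0.88
advanced,REM,4196.55,213.09,4409.64,1.62,0.43,3.86,0.64,0.09,1.09,0.72
mortality,VCM,4201.14,211.87,4413.01,0.85,0.22,1.84,0.78,0.46,1.11,0.52
mortality,REM,4200.83,212.61,4413.44,2.16,0.97,3.94,0.52,0.14,0.96,0.81
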