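structure_label,cell_label,binding_energy
unmodified_I,A1,3.32
unmodified_I,A2,3.34
unmodified_I,A3,4.80
unmodified_I,B1,2.70
unmodified_I,B2,3.93
unmodified_I,B3,7.74
unmodified_I,C1,5.00
unmodified_I,C2,4.99
unmodified_I,C3,8.49
unmodified_II,A1,3.97
unmodified_II,A2,4.63
unmodified_II,A3,7.02
unmodified_II,B1,3.38
unmodified_II,B2,3.88
unmodified_II,B3,8.10
unmodified_II,C1,5.62
unmodified_II,C2,4.41
unmodified_II,C3,6.78
unmodified_III,A1,4.35
unmodified_III,A2,3.86
unmodified_III,A3,9.33
unmodified_III,B1,3.81
unmodified_III,B2,4.05
unmodified_III,B3,9.27
unmodified_III,C1,4.36
unmodified_III,C2,3.75
unmodified_III,C3,6.91
hyperacetylated_I,A1,-2.55
hyperacetylated_I,A2,-2.21
hyperacetylated_I,A3,-0.24
hyperacetylated_I,B1,-3.51
hyperacetylated_I,B2,-3.88
hyperacetylated_I,B3,-1.02
hyperacetylated_I,C1,-2.80
hyperacetylated_I,C2,-3.28
hyperacetylated_I,C3,0.28
active_I,A1,0.89
active_I,A2,0.97
active_I,A3,1.32
active_I,B1,-1.43
active_I,B2,-0.79
active_I,B3,1.93
active_I,C1,-0.26
active_I,C2,-0.12
active_I,C3,1.54
inactive_I,A1,-0.70
inactive_I,A2,-0.55
inactive_I,A3,0.75
inactive_I,B1,-0.85
inactive_I,B2,-1.00
inactive_I,B3,0.69
inactive_I,C1,1.48
inactive_I,C2,-0.81
inactive_I,C3,-0.20
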