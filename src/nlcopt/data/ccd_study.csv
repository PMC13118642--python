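run_id,point_type,lipid_coded,lipid_actual,surfactant_coded,surfactant_actual,particle_size_mean,particle_size_sd,pdi_mean,pdi_sd,zeta_potential_mean,zeta_potential_sd,n
1,center,0,300.0,0,400.0,209.8,10.7,0.269,0.04,-13.8,0.51,3
2,center,0,300.0,0,400.0,197.8,2.5,0.216,0.02,-13.4,0.31,3
3,factorial,-1,200.0,-1,200.0,203.9,1.3,0.273,0.04,-16.7,0.42,3
4,center,0,300.0,0,400.0,231.7,3.2,0.267,0.01,-13.7,0.49,3
5,center,0,300.0,0,400.0,201.8,1.0,0.272,0.03,-11.9,1.10,3
6,factorial,-1,200.0,1,600.0,157.5,2.1,0.354,0.02,-10.6,0.80,3
7,center,0,300.0,0,400.0,227.6,5.4,0.260,0.02,-12.3,0.44,3
8,axial,0,300.0,1.414,682.8,175.7,1.4,0.177,0.01,-7.0,0.24,3
9,axial,-1.414,158.6,0,400.0,263.6,7.0,0.432,0.01,-8.5,0.20,3
10,factorial,1,400.0,-1,200.0,438.6,15.9,0.511,0.01,-12.9,0.40,3
11,factorial,1,400.0,1,600.0,286.0,1.2,0.320,0.02,-8.0,0.68,3
12,axial,1.414,441.4,0,400.0,376.3,8.6,0.484,0.04,-11.2,0.40,3
13,axial,0,300.0,-1.414,117.2,642.9,41.9,0.672,0.02,-15.8,0.67,3
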