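run_id,omega_rpm,bead_loading,bead_size_um,qgen_J_min,ua_J_min_C,fit_rmse_C
1,2000,0.4,200,755.2,47.79,0.40
2,2000,0.4,400,1616,103.5,0.46
3,2000,0.4,800,787.4,48.08,0.56
4,2000,0.5,200,441.4,25.82,0.32
5,2000,0.5,400,720.8,40.18,0.33
6,2000,0.5,800,1296,72.88,0.39
7,2000,0.6,200,1343,68.63,0.44
8,2000,0.6,400,2625,131.9,0.15
9,2000,0.6,800,1822,89.95,0.50
10,3000,0.4,200,1402,53.92,0.55
11,3000,0.4,400,2938,107.0,0.57
12,3000,0.4,800,2798,101.0,0.66
13,3000,0.5,200,1837,61.49,0.40
14,3000,0.5,400,3243,107.3,0.72
15,3000,0.5,800,3307,107.4,0.83
16,3000,0.6,200,2624,94.08,0.43
17,3000,0.6,400,4598,128.2,0.76
18,3000,0.6,800,4542,124.4,0.80
19,4000,0.4,200,5075,135.1,0.42
20,4000,0.4,400,6266,162.7,0.41
21,4000,0.4,800,6245,162.5,0.51
22,4000,0.5,200,6116,162.7,0.90
23,4000,0.5,400,8490,220.0,0.30
24,4000,0.5,800,9359,238.1,0.60
25,4000,0.6,200,8383,208.9,0.62
26,4000,0.6,400,10600,261.7,0.28
27,4000,0.6,800,10740,171.9,0.34
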