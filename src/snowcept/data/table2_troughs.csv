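trough_id,avg_throughfall_mm,avg_interception_mm,n_stems,canopy_density_pct,lai,dbh_cm,ba,canopy_height_m,canopy_width_m,tree_height_m,slope
1,9.6,2.1,2,47.6,2.41,43.2,63.4,21.4,8.6,26.3,0
2,9.5,2.2,2,54.6,2.13,59.0,109.3,27.5,12.0,33.5,0
3,9.4,2.3,4,43.9,1.50,48.3,23.0,22.5,10.2,28.4,0
4,8.1,3.6,6,60.5,2.08,43.3,74.2,18.5,7.2,22.9,29
5,9.5,2.3,4,53.1,2.05,32.1,45.1,13.8,6.4,20.4,22
6,8.2,3.5,5,63.6,2.90,36.7,53.0,21.9,8.2,27.6,17
7,8.2,3.5,3,63.8,2.50,40.8,64.0,19.1,10.2,24.5,8
8,10.8,1.1,2,45.5,1.42,67.7,144.3,18.6,9.6,26.6,25
9,10.1,1.7,1,31.0,1.09,62.4,122.3,18.9,11.3,27.4,21
10,10.4,1.4,3,39.2,1.46,55.0,100.2,22.9,9.9,30.1,5
11,9.4,2.4,2,51.2,2.56,60.0,114.5,20.9,11.4,28.4,17
12,9.7,2.0,6,56.2,2.60,31.4,53.9,12.3,6.1,20.5,38
13,9.5,2.2,2,55.1,2.77,46.9,79.2,14.5,7.8,20.8,38
14,9.7,2.0,2,36.3,3.44,34.5,53.4,8.9,5.5,13.0,56
15,10.3,1.4,4,62.4,3.03,54.2,92.8,16.9,10.3,25.8,56
16,9.5,2.2,3,25.8,0.73,8.7,2.9,3.5,2.9,6.2,56
17,8.5,3.2,3,45.3,1.40,44.5,68.3,17.6,8.5,24.7,56
18,7.1,2.0,4,54.2,1.65,38.3,54.2,14.4,9.5,23.6,31
19,6.9,2.6,3,52.8,2.16,47.3,40.0,20.0,8.0,26.0,31
20,6.9,2.5,4,69.3,2.58,38.4,55.6,15.6,8.8,25.3,31
21,7.4,3.0,3,56.3,2.27,29.5,45.3,12.3,7.6,18.7,31
22,8.2,2.3,5,53.2,2.04,42.3,62.0,15.1,10.3,23.0,49
23,7.7,3.0,2,42.4,1.28,59.2,113.2,14.5,9.1,21.9,49
24,7.9,4.3,5,45.3,1.33,32.0,32.2,16.3,8.3,22.8,49
25,7.4,4.7,1,53.0,1.67,59.8,112.3,20.7,11.4,30.0,49
26,7.8,3.0,2,57.1,4.33,51.4,128.5,17.1,9.5,20.6,35
27,7.3,3.3,1,44.2,1.48,29.7,27.7,20.8,7.6,24.0,35
28,6.2,3.1,3,64.5,3.67,51.1,84.4,16.9,10.2,24.0,35
29,5.8,2.8,8,68.0,3.22,20.3,17.9,9.6,5.4,12.4,35
30,6.2,3.2,2,52.4,2.19,43.2,63.4,21.4,8.6,26.3,0
31,6.5,2.7,3,57.0,2.74,37.5,36.0,17.5,9.0,26.9,0
32,6.1,3.1,7,62.6,3.01,27.0,44.2,9.9,6.1,16.5,0
33,6.5,2.8,3,49.9,2.26,28.5,31.8,13.6,5.9,19.5,0
34,5.9,3.3,3,46.1,1.50,54.1,105.1,17.0,10.6,27.0,0
35,6.2,3.1,3,58.5,2.16,35.5,67.2,14.3,8.9,23.4,0
36,4.7,4.6,4,63.7,2.64,36.8,102.5,21.9,11.0,29.8,0
37,7.5,1.7,1,23.7,0.63,49.0,75.4,16.0,9.2,26.4,35
38,6.3,2.9,1,47.4,1.81,41.0,61.8,17.9,8.6,25.3,34
39,5.8,3.5,2,42.6,1.47,32.3,34.0,12.9,9.0,17.7,30
40,5.7,3.6,4,58.6,2.22,35.3,51.0,14.8,8.6,20.5,23
41,5.3,4.0,5,63.3,2.32,41.6,65.0,19.8,8.5,25.7,23
42,5.2,4.1,6,65.5,3.14,39.4,60.8,19.3,8.7,24.5,10
43,5.5,3.8,3,60.9,2.78,40.8,64.0,19.1,10.2,24.5,8
44,5.5,3.8,8,72.0,2.77,42.0,73.3,15.7,23.6,8.1,0
45,5.9,3.4,4,65.5,4.11,37.1,56.0,15.5,22.2,7.4,7
46,5.9,3.3,5,55.6,1.99,35.2,56.8,14.4,20.2,6.9,17
47,7.7,1.5,1,40.5,1.50,60.0,90.0,23.0,10.0,29.0,0
48,6.1,3.1,3,51.9,1.75,34.5,52.6,14.5,18.0,7.1,21
49,7.0,2.2,2,38.2,1.33,41.6,54.9,17.9,23.9,8.2,26
50,7.8,1.4,2,46.3,1.85,18.0,10.5,11.1,14.9,5.9,37
51,6.0,3.3,3,54.7,2.04,43.9,69.1,22.7,29.1,9.9,0
52,7.7,1.6,1,30.6,1.40,57.6,104.2,26.7,37.2,10.0,0
53,6.7,2.5,4,49.5,2.78,38.1,52.4,13.7,22.2,6.1,37
54,7.0,2.3,2,51.2,2.56,60.0,114.5,20.9,28.4,11.4,17
55,6.8,2.4,2,41.7,1.91,69.4,154.4,23.3,35.6,9.3,17
56,6.2,3.0,4,65.2,3.36,47.6,85.2,14.8,25.8,8.5,9
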