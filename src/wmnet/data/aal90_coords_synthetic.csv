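index,x,y,z
1,-29.69,-19.31,34.65
2,29.69,-19.31,34.65
3,-31.89,26.98,12.57
4,31.89,26.98,12.57
5,-26.79,25.1,18.97
6,26.79,25.1,18.97
7,-22.7,28.57,26.45
8,22.7,28.57,26.45
9,-29.18,34.24,34.51
10,29.18,34.24,34.51
11,-19.07,38.11,20.29
12,19.07,38.11,20.29
13,-24.97,38.91,17.99
14,24.97,38.91,17.99
15,-32.68,45.45,31.89
16,32.68,45.45,31.89
17,-27.2,-13.67,48.68
18,27.2,-13.67,48.68
19,-18.48,57.4,39.14
20,18.48,57.4,39.14
21,-26.96,56.59,8.95
22,26.96,56.59,8.95
23,-27.39,56.28,18.05
24,27.39,56.28,18.05
25,-25.29,67.31,33.26
26,25.29,67.31,33.26
27,-23.82,70.24,32.87
28,23.82,70.24,32.87
29,-41.32,-8.38,-7.45
30,41.32,-8.38,-7.45
31,-14.9,-22.59,3.94
32,14.9,-22.59,3.94
33,-17.3,-27.81,16.11
34,17.3,-27.81,16.11
35,-6.48,-22.95,18.2
36,6.48,-22.95,18.2
37,-10.23,-12.55,26.1
38,10.23,-12.55,26.1
39,-15.87,-10.59,7.92
40,15.87,-10.59,7.92
41,-5.49,-11.72,16.46
42,5.49,-11.72,16.46
43,-17.49,-97.15,4.59
44,17.49,-97.15,4.59
45,-16.53,-84.51,8.25
46,16.53,-84.51,8.25
47,-14.53,-85.65,14.59
48,14.53,-85.65,14.59
49,-12.14,-85.3,24.54
50,12.14,-85.3,24.54
51,-17.92,-71.88,-4.52
52,17.92,-71.88,-4.52
53,-26.67,-65.78,1.11
54,26.67,-65.78,1.11
55,-46.54,-32.02,-25.2
56,46.54,-32.02,-25.2
57,-27.18,-14.38,49.36
58,27.18,-14.38,49.36
59,-35.07,-70.42,30.56
60,35.07,-70.42,30.56
61,-30.28,-59.72,41.55
62,30.28,-59.72,41.55
63,-31.03,-61.5,53.67
64,31.03,-61.5,53.67
65,-34.08,-50.27,60.55
66,34.08,-50.27,60.55
67,-33.51,-52.33,36.3
68,33.51,-52.33,36.3
69,-28.09,-6.51,61.28
70,28.09,-6.51,61.28
71,-20.17,-16.21,-11.29
72,20.17,-16.21,-11.29
73,-18.05,-12.97,4.67
74,18.05,-12.97,4.67
75,-19.04,3.23,9.18
76,19.04,3.23,9.18
77,-12.8,-2.94,19.47
78,12.8,-2.94,19.47
79,-55.05,-32.75,-21.54
80,55.05,-32.75,-21.54
81,-42.33,-27.91,-6.65
82,42.33,-27.91,-6.65
83,-44.67,-18.0,-6.93
84,44.67,-18.0,-6.93
85,-54.88,-16.07,-28.28
86,54.88,-16.07,-28.28
87,-50.63,-14.2,-16.67
88,50.63,-14.2,-16.67
89,-49.53,-1.49,-15.14
90,49.53,-1.49,-15.14
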