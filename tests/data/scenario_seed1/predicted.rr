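PFRMAT RR
LMSYADTWFHVKGTGKPMCAVSTMTHLSDHDLYDIKWFMGASCGLLDYRYCRGMWGREHYKMGDKPLSIPSWKARMVLICLPSVFNTGHTNMQMYSCDMTCQSSVENTIELCFVQVTVHLPGWATPGRKTYGLFQPTTYY
MODEL 1
14 98 0 8 0.675400
16 21 0 8 0.726700
16 34 0 8 0.878800
16 35 0 8 0.934200
16 36 0 8 0.965400
16 37 0 8 0.900900
16 38 0 8 0.706900
16 39 0 8 0.979700
16 40 0 8 0.974600
16 105 0 8 0.919000
16 106 0 8 0.748200
16 107 0 8 0.859600
16 108 0 8 0.844700
17 22 0 8 0.867000
17 34 0 8 0.942900
17 35 0 8 0.811800
17 36 0 8 0.879900
17 37 0 8 0.815800
17 39 0 8 0.869600
17 105 0 8 0.715100
17 106 0 8 0.740000
17 108 0 8 0.806100
17 109 0 8 0.885600
18 23 0 8 0.719800
18 32 0 8 0.778800
18 33 0 8 0.933600
18 34 0 8 0.782100
18 36 0 8 0.736800
18 105 0 8 0.881800
18 106 0 8 0.770600
18 107 0 8 0.851400
18 108 0 8 0.856900
18 109 0 8 0.925800
18 110 0 8 0.964700
19 24 0 8 0.788100
19 31 0 8 0.840700
19 32 0 8 0.880700
19 33 0 8 0.710700
19 35 0 8 0.940000
19 105 0 8 0.746600
19 106 0 8 0.827400
19 107 0 8 0.810500
19 108 0 8 0.759100
19 109 0 8 0.857600
19 110 0 8 0.735500
20 25 0 8 0.941600
20 30 0 8 0.974000
20 33 0 8 0.838400
20 34 0 8 0.878000
20 35 0 8 0.729100
20 36 0 8 0.885400
20 106 0 8 0.986400
20 107 0 8 0.786900
20 109 0 8 0.779200
20 110 0 8 0.974700
20 112 0 8 0.780800
21 29 0 8 0.762900
21 30 0 8 0.857100
21 31 0 8 0.801800
21 33 0 8 0.878000
21 34 0 8 0.726600
21 35 0 8 0.987600
21 107 0 8 0.951700
21 108 0 8 0.897600
21 109 0 8 0.820800
21 110 0 8 0.789400
21 111 0 8 0.775600
21 112 0 8 0.854700
21 113 0 8 0.780100
22 27 0 8 0.837100
22 29 0 8 0.863100
22 31 0 8 0.730200
22 32 0 8 0.739800
22 33 0 8 0.866400
22 34 0 8 0.907700
22 108 0 8 0.822700
22 111 0 8 0.748300
22 113 0 8 0.919600
22 114 0 8 0.804700
23 28 0 8 0.968500
23 29 0 8 0.747100
23 30 0 8 0.814400
23 31 0 8 0.979200
23 32 0 8 0.907100
23 109 0 8 0.905700
23 110 0 8 0.933500
23 111 0 8 0.881700
24 29 0 8 0.809200
24 30 0 8 0.958600
24 31 0 8 0.776800
24 32 0 8 0.783700
24 67 0 8 0.527300
24 110 0 8 0.705800
24 111 0 8 0.790200
24 112 0 8 0.805300
24 114 0 8 0.862900
24 115 0 8 0.969600
25 30 0 8 0.929600
25 31 0 8 0.822300
25 111 0 8 0.748700
25 112 0 8 0.724400
25 113 0 8 0.774000
25 114 0 8 0.804100
25 115 0 8 0.807400
25 116 0 8 0.907900
26 31 0 8 0.901100
26 113 0 8 0.957400
26 114 0 8 0.818300
26 115 0 8 0.836700
26 117 0 8 0.823000
26 118 0 8 0.826500
26 119 0 8 0.844700
26 120 0 8 0.899200
26 121 0 8 0.876000
27 114 0 8 0.737900
27 115 0 8 0.974000
27 118 0 8 0.939700
27 121 0 8 0.895900
27 122 0 8 0.866700
28 33 0 8 0.845600
28 119 0 8 0.727400
28 121 0 8 0.751400
28 123 0 8 0.884300
28 124 0 8 0.762100
29 34 0 8 0.720600
29 119 0 8 0.720000
29 120 0 8 0.941900
29 121 0 8 0.737300
29 122 0 8 0.857400
29 123 0 8 0.759900
29 124 0 8 0.952500
29 125 0 8 0.846200
30 120 0 8 0.910400
30 121 0 8 0.928300
30 122 0 8 0.857300
30 123 0 8 0.951200
30 125 0 8 0.984500
30 126 0 8 0.940800
31 121 0 8 0.986100
31 122 0 8 0.844200
31 123 0 8 0.938200
31 124 0 8 0.899900
31 125 0 8 0.801900
31 126 0 8 0.768600
31 127 0 8 0.923400
32 122 0 8 0.747200
32 123 0 8 0.724000
32 124 0 8 0.806900
32 125 0 8 0.962700
33 38 0 8 0.845700
33 72 0 8 0.553600
33 123 0 8 0.729700
33 124 0 8 0.948200
33 125 0 8 0.701100
33 126 0 8 0.920400
33 127 0 8 0.757900
33 128 0 8 0.876700
34 39 0 8 0.873800
34 84 0 8 0.699700
34 124 0 8 0.829000
34 125 0 8 0.936100
34 126 0 8 0.844200
34 127 0 8 0.848800
34 128 0 8 0.989600
34 129 0 8 0.786000
34 130 0 8 0.807800
35 40 0 8 0.852100
35 125 0 8 0.958400
35 127 0 8 0.773000
35 128 0 8 0.826500
35 130 0 8 0.946400
35 131 0 8 0.758300
36 41 0 8 0.937700
36 127 0 8 0.938400
36 128 0 8 0.770700
36 129 0 8 0.977600
36 130 0 8 0.783800
36 131 0 8 0.738500
37 42 0 8 0.803900
37 127 0 8 0.874900
37 128 0 8 0.825400
38 128 0 8 0.911700
38 129 0 8 0.780800
38 130 0 8 0.974300
39 129 0 8 0.766200
39 130 0 8 0.904500
40 72 0 8 0.625100
40 130 0 8 0.949900
40 131 0 8 0.779300
41 131 0 8 0.988100
49 119 0 8 0.533900
55 121 0 8 0.446400
66 123 0 8 0.379300
72 100 0 8 0.973100
76 105 0 8 0.438400
88 138 0 8 0.893200
89 120 0 8 0.326800
98 139 0 8 0.962800
101 137 0 8 0.465600
101 140 0 8 0.506800
102 125 0 8 0.468900
102 138 0 8 0.871000
104 127 0 8 0.602400
105 127 0 8 0.791400
105 128 0 8 0.710200
105 129 0 8 0.713000
105 131 0 8 0.792400
106 111 0 8 0.792400
106 126 0 8 0.807100
106 127 0 8 0.812300
106 128 0 8 0.721800
106 131 0 8 0.899600
107 125 0 8 0.906400
107 126 0 8 0.722600
107 127 0 8 0.917600
107 128 0 8 0.753700
107 131 0 8 0.798700
108 113 0 8 0.829200
108 124 0 8 0.857600
108 125 0 8 0.868800
108 126 0 8 0.880300
108 127 0 8 0.741100
108 128 0 8 0.937500
108 129 0 8 0.964900
109 114 0 8 0.952900
109 123 0 8 0.892800
109 125 0 8 0.938000
109 126 0 8 0.932300
109 127 0 8 0.932400
109 128 0 8 0.830600
110 115 0 8 0.745300
110 124 0 8 0.982300
110 125 0 8 0.958700
110 127 0 8 0.702800
110 128 0 8 0.970000
111 116 0 8 0.812200
111 122 0 8 0.800800
111 123 0 8 0.978300
111 125 0 8 0.776600
111 127 0 8 0.761100
111 138 0 8 0.483200
112 120 0 8 0.908500
112 121 0 8 0.731600
112 123 0 8 0.718100
113 118 0 8 0.837200
113 119 0 8 0.957500
113 120 0 8 0.722400
113 123 0 8 0.715500
113 125 0 8 0.981700
114 119 0 8 0.826300
114 120 0 8 0.731200
114 121 0 8 0.799000
114 122 0 8 0.738800
114 124 0 8 0.762400
114 138 0 8 0.732900
115 120 0 8 0.737800
115 121 0 8 0.890000
115 122 0 8 0.848300
115 123 0 8 0.920000
116 121 0 8 0.956700
116 122 0 8 0.967400
117 122 0 8 0.709900
119 124 0 8 0.783500
120 125 0 8 0.731400
121 126 0 8 0.773200
122 127 0 8 0.915000
125 130 0 8 0.905800
END
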