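# DeWeX leg 2 (April 2013) surface station survey of Minidiscus spp.
# Columns: sampling date (DD/MM/YY), station id, latitude (decimal deg N),
# longitude (decimal deg E), Minidiscus cell concentration (cells per litre),
# percent contribution to total diatom abundance, percent contribution to
# particulate organic carbon, percent contribution to biogenic silica.
# Missing contribution values (printed as an em dash in the source table)
# are stored as "—". Two rows (stations 19 and 31) are typographically
# ambiguous in some renderings of the source; the reading used here keeps
# two-decimal longitudes (4.72 / 557645 and 3.62 / 1025696), consistent with
# every unambiguous row.
date,station,latitude,longitude,minidiscus_cells,pct_diatom_abundance,pct_poc,pct_bsi
05/04/13,1,42.91,6.12,0,0,—,0
06/04/13,6,42.05,6.00,15250,52.1,—,0.2
07/04/13,9,42.03,4.80,76453,81.9,1.2,2.1
07/04/13,13,42.31,3.51,0,0,—,0
08/04/13,19,42.02,4.72,557645,98.6,10.8,9.5
09/04/13,22,40.95,4.51,454725,95.1,3.8,6.0
10/04/13,25,40.26,4.19,2711,96.4,0.0,0.5
10/04/13,28,41.19,3.89,162228,84.5,—,5.4
11/04/13,31,41.81,3.62,1025696,98.4,6.4,14.6
11/04/13,37,42.00,5.00,268172,98.8,1.6,3.7
12/04/13,42,42.88,7.40,0,0,—,0
13/04/13,45,43.63,7.39,0,0,0,0
13/04/13,48,43.42,7.87,0,0,0,0
14/04/13,51,42.81,8.53,0,0,0,0
15/04/13,55,41.71,8.46,0,0,—,0
16/04/13,61,42.03,6.00,1300,100,0,0
17/04/13,67,40.82,7.91,0,0,—,0
18/04/13,71,40.38,7.16,0,0,0,0
18/04/13,73,40.08,6.37,0,0,0,0
19/04/13,74,41.98,5.02,5819040,99.0,18.3,99.4
19/04/13,78,41.12,5.63,0,0,0,0
21/04/13,81,40.40,6.15,174368,98.0,1.2,19.6
22/04/13,83,40.33,6.06,425316,99.1,3.6,18.9
22/04/13,84,40.29,6.02,91554,84.3,0.6,5.1
22/04/13,85,40.24,5.95,274234,98.2,2.3,13.6
22/04/13,87,40.17,5.87,0,0,0,0
22/04/13,88,40.56,5.96,5746,98.8,0.1,4.7
22/04/13,89,40.44,5.97,0,0,0,0
23/04/13,91,40.30,5.97,33212,87.5,0.3,3.6
23/04/13,95,40.22,5.33,0,0,0,0
24/04/13,98,40.01,4.42,0,0,0,0
24/04/13,99,41.98,5.02,4307310,99.4,26.4,36
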