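{
 "stages": [
  "s1",
  "s2",
  "s3",
  "s4",
  "s5",
  "s6"
 ],
 "periods": [
  "preMZT",
  "early",
  "early",
  "middle",
  "middle",
  "late"
 ],
 "tei_omega0": [
  0.15954545454545455,
  0.1419230769230769,
  0.11266666666666666,
  0.10378378378378378,
  0.12828571428571425,
  0.1606451612903226
 ],
 "delta_em_omega0": 0.011260122760122768,
 "tei_phylostratum": [
  1.391304347826087,
  1.78125,
  2.026315789473684,
  2.2857142857142856,
  3.0238095238095237,
  3.4390243902439024
 ],
 "delta_em_phylostratum": -0.7509790100250626,
 "tei_paralog_count": [
  1.7826086956521738,
  2.875,
  2.736842105263158,
  2.5,
  3.5714285714285716,
  4.487804878048781
 ],
 "delta_em_paralog_count": -0.22979323308270683,
 "tei_connectivity": [
  24.17391304347826,
  19.15625,
  21.31578947368421,
  23.047619047619047,
  17.0,
  12.487804878048781
 ],
 "delta_em_connectivity": 0.21221021303257714,
 "pleiotropy": {
  "flags": {
   "g01": false,
   "g02": true,
   "g03": false,
   "g04": true,
   "g05": true,
   "g06": true,
   "g07": true,
   "g08": false,
   "g09": false,
   "g10": true,
   "g_const": true,
   "g_testis": false
  },
  "n_expressed": [
   4,
   7,
   9,
   10,
   8,
   9
  ],
  "n_pleiotropic": [
   3,
   5,
   7,
   7,
   5,
   6
  ],
  "proportion": [
   0.75,
   0.7142857142857143,
   0.7777777777777778,
   0.7,
   0.625,
   0.6666666666666666
  ],
  "chi2": 0.17184944684944684,
  "df": 5
 },
 "tau": {
  "g01": 0.0,
  "g02": 0.3,
  "g03": 0.5833333333333334,
  "g04": 0.7,
  "g05": 0.625,
  "g06": 0.75,
  "g07": 0.5,
  "g08": 0.9166666666666667,
  "g09": 0.875,
  "g10": 0.0,
  "g_const": 0.0,
  "g_testis": 1.0
 },
 "retrogene_medians": [
  0.0,
  0.0,
  1.0,
  2.0,
  6.0,
  8.0
 ],
 "retrogene_rho": 0.9856107606091623
}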