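medium,energy_MeV,mass_stopping_power_MeV_cm2_per_g
water,0.05,525.877
water,0.0520526,536.563
water,0.0541894,547.465
water,0.0564139,558.589
water,0.0587298,569.939
water,0.0611407,581.52
water,0.0636506,593.336
water,0.0662636,605.392
water,0.0689838,617.693
water,0.0718156,630.244
water,0.0747638,643.05
water,0.0778329,656.116
water,0.081028,669.448
water,0.0843543,683.051
water,0.0878172,696.93
water,0.0914222,711.091
water,0.0951752,725.54
water,0.0990823,740.282
water,0.10315,755.324
water,0.107384,770.672
water,0.111792,786.331
water,0.116382,802.309
water,0.121159,818.611
water,0.126133,835.244
water,0.131311,852.216
water,0.136701,869.532
water,0.142313,887.2
water,0.148155,905.228
water,0.154237,923.621
water,0.160569,942.388
water,0.16716,961.537
water,0.174023,981.075
water,0.181166,1001.01
water,0.188603,1021.35
water,0.196346,1042.1
water,0.204406,1063.28
water,0.212797,1084.88
water,0.221533,1106.93
water,0.230627,1129.42
water,0.240095,1152.37
water,0.249951,1175.78
water,0.260212,1199.67
water,0.270894,1224.05
water,0.282014,1248.92
water,0.293591,1274.3
water,0.305643,1300.19
water,0.31819,1326.61
water,0.331253,1353.56
water,0.344851,1381.07
water,0.359007,1409.13
water,0.373745,1437.76
water,0.389088,1466.98
water,0.40506,1496.78
water,0.421689,1527.2
water,0.438999,1558.23
water,0.457021,1589.89
water,0.475782,1622.2
water,0.495314,1655.16
water,0.515647,1688.79
water,0.536815,1723.1
water,0.558852,1758.12
water,0.581793,1793.84
water,0.605677,1830.29
water,0.630541,1867.48
water,0.656425,1905.42
water,0.683372,1944.14
water,0.711425,1983.64
water,0.74063,2023.95
water,0.771034,2023.43
water,0.802686,2021.16
water,0.835637,2017.17
water,0.869941,2011.53
water,0.905653,2004.3
water,0.942832,1995.52
water,0.981536,1985.26
water,1.02183,1973.57
water,1.06378,1960.52
water,1.10745,1946.15
water,1.15291,1930.52
water,1.20024,1913.71
water,1.24951,1895.76
water,1.3008,1876.73
water,1.3542,1856.7
water,1.40979,1835.7
water,1.46767,1813.81
water,1.52792,1791.08
water,1.59064,1767.57
water,1.65594,1743.35
water,1.72391,1718.45
water,1.79468,1692.95
water,1.86836,1666.9
water,1.94506,1640.34
water,2.0249,1613.35
water,2.10803,1585.96
water,2.19457,1558.23
water,2.28465,1530.21
water,2.37844,1501.94
water,2.47608,1473.48
water,2.57773,1444.88
water,2.68355,1416.16
water,2.79371,1387.39
water,2.90839,1358.59
water,3.02779,1329.81
water,3.15208,1301.08
water,3.28148,1272.45
water,3.41619,1243.93
water,3.55643,1215.58
water,3.70242,1187.42
water,3.85441,1159.47
water,4.01264,1131.76
water,4.17736,1104.33
water,4.34885,1077.19
water,4.52738,1050.36
water,4.71323,1023.87
water,4.90671,997.725
water,5.10814,971.956
water,5.31784,946.572
water,5.53614,921.587
water,5.76341,897.013
water,6,872.862
air,0.05,438.995
air,0.0520526,447.915
air,0.0541894,457.017
air,0.0564139,466.303
air,0.0587298,475.778
air,0.0611407,485.445
air,0.0636506,495.309
air,0.0662636,505.373
air,0.0689838,515.642
air,0.0718156,526.119
air,0.0747638,536.81
air,0.0778329,547.717
air,0.081028,558.846
air,0.0843543,570.202
air,0.0878172,581.788
air,0.0914222,593.609
air,0.0951752,605.671
air,0.0990823,617.978
air,0.10315,630.534
air,0.107384,643.346
air,0.111792,656.419
air,0.116382,669.757
air,0.121159,683.365
air,0.126133,697.251
air,0.131311,711.418
air,0.136701,725.874
air,0.142313,740.623
air,0.148155,755.672
air,0.154237,771.027
air,0.160569,786.693
air,0.16716,802.678
air,0.174023,818.988
air,0.181166,835.629
air,0.188603,852.608
air,0.196346,869.933
air,0.204406,887.609
air,0.212797,905.645
air,0.221533,924.047
air,0.230627,942.822
air,0.240095,961.98
air,0.249951,981.526
air,0.260212,1001.47
air,0.270894,1021.82
air,0.282014,1042.58
air,0.293591,1063.77
air,0.305643,1085.38
air,0.31819,1107.44
air,0.331253,1129.94
air,0.344851,1152.9
air,0.359007,1176.32
air,0.373745,1200.22
air,0.389088,1224.61
air,0.40506,1249.5
air,0.421689,1274.88
air,0.438999,1300.79
air,0.457021,1327.22
air,0.475782,1354.19
air,0.495314,1381.7
air,0.515647,1409.78
air,0.536815,1438.42
air,0.558852,1467.65
air,0.581793,1497.47
air,0.605677,1527.9
air,0.630541,1558.95
air,0.656425,1590.62
air,0.683372,1622.94
air,0.711425,1655.92
air,0.74063,1689.57
air,0.771034,1723.9
air,0.802686,1758.93
air,0.835637,1758.64
air,0.869941,1756.76
air,0.905653,1753.34
air,0.942832,1748.42
air,0.981536,1742.06
air,1.02183,1734.32
air,1.06378,1725.25
air,1.10745,1714.89
air,1.15291,1703.31
air,1.20024,1690.56
air,1.24951,1676.7
air,1.3008,1661.77
air,1.3542,1645.85
air,1.40979,1628.97
air,1.46767,1611.2
air,1.52792,1592.59
air,1.59064,1573.19
air,1.65594,1553.07
air,1.72391,1532.26
air,1.79468,1510.83
air,1.86836,1488.83
air,1.94506,1466.31
air,2.0249,1443.32
air,2.10803,1419.9
air,2.19457,1396.11
air,2.28465,1371.99
air,2.37844,1347.59
air,2.47608,1322.96
air,2.57773,1298.13
air,2.68355,1273.15
air,2.79371,1248.06
air,2.90839,1222.9
air,3.02779,1197.7
air,3.15208,1172.5
air,3.28148,1147.34
air,3.41619,1122.25
air,3.55643,1097.26
air,3.70242,1072.39
air,3.85441,1047.68
air,4.01264,1023.15
air,4.17736,998.833
air,4.34885,974.743
air,4.52738,950.905
air,4.71323,927.337
air,4.90671,904.059
air,5.10814,881.087
air,5.31784,858.436
air,5.53614,836.121
air,5.76341,814.153
air,6,792.544
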