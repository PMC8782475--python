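t,hwma_stat,hwma_lcl,hwma_ucl,hwma_ooc,dhwma_stat,dhwma_lcl,dhwma_ucl,dhwma_ooc,hhwma_stat,hhwma_lcl,hhwma_ucl,hhwma_ooc
1,1557.50,824.33,1805.67,No,1436.25,1145.40,1484.60,No,1496.88,1046.98,1583.02,No
2,1557.50,621.09,2008.91,No,1436.25,935.77,1694.23,No,1496.88,868.31,1761.69,No
3,1557.50,714.06,1915.94,No,1436.25,965.37,1664.63,No,1496.88,866.08,1763.92,No
4,1557.50,748.42,1881.58,No,1436.25,997.71,1632.29,No,1496.88,898.62,1731.38,No
5,1479.00,766.41,1863.59,No,1397.00,1020.74,1609.26,No,1438.00,922.92,1707.08,No
6,1495.75,777.50,1852.50,No,1405.38,1037.53,1592.47,No,1450.56,940.66,1689.34,No
7,1722.25,785.02,1844.98,No,1518.63,1050.27,1579.73,No,1620.44,954.03,1675.97,No
8,1784.50,790.45,1839.55,No,1549.75,1060.26,1569.74,No,1667.13,964.42,1665.58,Yes
9,1745.00,794.57,1835.43,No,1530.00,1068.31,1561.69,No,1637.50,972.72,1657.28,No
10,1534.75,797.79,1832.21,No,1424.88,1074.95,1555.05,No,1479.81,979.51,1650.49,No
11,1605.50,800.38,1829.62,No,1460.25,1080.51,1549.49,No,1532.88,985.15,1644.85,No
12,1605.50,802.51,1827.49,No,1460.25,1085.24,1544.76,No,1532.88,989.92,1640.08,No
13,917.75,804.30,1825.71,No,1116.38,1089.32,1540.68,No,1017.06,994.01,1635.99,No
14,778.25,805.81,1824.19,Yes,1046.63,1092.88,1537.12,Yes,912.44,997.54,1632.46,Yes
15,1349.00,807.11,1822.89,No,1332.00,1096.00,1534.00,No,1340.50,1000.64,1629.36,No
16,983.50,808.24,1821.76,No,1149.25,1098.77,1531.23,No,1066.38,1003.37,1626.63,No
17,1380.75,809.23,1820.77,No,1347.88,1101.24,1528.76,No,1364.31,1005.79,1624.21,No
18,1535.00,810.11,1819.89,No,1425.00,1103.46,1526.54,No,1480.00,1007.96,1622.04,No
19,1436.75,810.89,1819.11,No,1375.88,1105.47,1524.53,No,1406.31,1009.91,1620.09,No
20,1583.75,811.58,1818.42,No,1449.38,1107.29,1522.71,No,1516.56,1011.67,1618.33,No
21,1149.00,812.21,1817.79,No,1232.00,1108.95,1521.05,No,1190.50,1013.28,1616.72,No
22,1202.50,812.78,1817.22,No,1258.75,1110.47,1519.53,No,1230.63,1014.74,1615.26,No
23,974.75,813.30,1816.70,No,1144.88,1111.86,1518.14,No,1059.81,1016.08,1613.92,No
24,728.50,813.78,1816.22,Yes,1021.75,1113.15,1516.85,Yes,875.13,1017.32,1612.68,Yes
25,1470.00,814.21,1815.79,No,1392.50,1114.35,1515.65,No,1431.25,1018.46,1611.54,No
26,1371.50,814.61,1815.39,No,1343.25,1115.45,1514.55,No,1357.38,1019.51,1610.49,No
27,1342.75,814.98,1815.02,No,1328.88,1116.49,1513.51,No,1335.81,1020.49,1609.51,No
28,1138.00,815.33,1814.67,No,1226.50,1117.45,1512.55,No,1182.25,1021.40,1608.60,No
29,1416.00,815.65,1814.35,No,1365.50,1118.35,1511.65,No,1390.75,1022.26,1607.75,No
30,1473.75,815.94,1814.06,No,1394.38,1119.19,1510.81,No,1434.06,1023.05,1606.95,No
31,1207.75,816.22,1813.78,No,1261.38,1119.98,1510.02,No,1234.56,1023.80,1606.20,No
32,1131.00,816.48,1813.52,No,1223.00,1120.73,1509.27,No,1177.00,1024.50,1605.50,No
33,788.75,816.72,1813.28,Yes,1051.88,1121.43,1508.57,Yes,920.31,1025.16,1604.84,Yes
34,788.75,816.95,1813.05,Yes,1051.88,1122.09,1507.91,Yes,920.31,1025.78,1604.22,Yes
35,1277.00,817.17,1812.83,No,1296.00,1122.72,1507.28,No,1286.50,1026.37,1603.63,No
36,1607.75,817.37,1812.63,No,1461.38,1123.31,1506.69,No,1534.56,1026.93,1603.07,No
37,1721.50,817.56,1812.44,No,1518.25,1123.88,1506.12,Yes,1619.88,1027.45,1602.55,Yes
38,1716.75,817.74,1812.26,No,1515.88,1124.41,1505.59,Yes,1616.31,1027.95,1602.05,Yes
39,1377.50,817.92,1812.08,No,1346.25,1124.92,1505.08,No,1361.88,1028.43,1601.57,No
40,1574.75,818.08,1811.92,No,1444.88,1125.41,1504.59,No,1509.81,1028.88,1601.12,No
41,1418.25,818.24,1811.77,No,1366.63,1125.87,1504.13,No,1392.44,1029.31,1600.69,No
42,1035.75,818.38,1811.62,No,1175.38,1126.31,1503.69,No,1105.56,1029.72,1600.28,No
43,780.25,818.52,1811.48,Yes,1047.63,1126.74,1503.26,Yes,913.94,1030.11,1599.89,Yes
44,883.75,818.66,1811.34,No,1099.38,1127.14,1502.86,Yes,991.56,1030.49,1599.51,Yes
45,1226.75,818.79,1811.21,No,1270.88,1127.53,1502.47,No,1248.81,1030.84,1599.16,No
46,1446.75,818.91,1811.09,No,1380.88,1127.90,1502.10,No,1413.81,1031.19,1598.81,No
47,1332.75,819.03,1810.97,No,1323.88,1128.25,1501.75,No,1328.31,1031.52,1598.48,No
48,1307.75,819.14,1810.86,No,1311.38,1128.59,1501.41,No,1309.56,1031.83,1598.17,No
49,1179.75,819.25,1810.75,No,1247.38,1128.92,1501.08,No,1213.56,1032.13,1597.87,No
50,1011.00,819.35,1810.65,No,1163.00,1129.24,1500.76,No,1087.00,1032.42,1597.58,No
51,991.25,819.45,1810.55,No,1153.13,1129.54,1500.46,No,1072.19,1032.70,1597.30,No
52,1344.75,819.54,1810.46,No,1329.88,1129.83,1500.17,No,1337.31,1032.97,1597.03,No
53,1239.00,819.64,1810.37,No,1277.00,1130.12,1499.88,No,1258.00,1033.23,1596.77,No
54,1086.75,819.72,1810.28,No,1200.88,1130.39,1499.61,No,1143.81,1033.48,1596.52,No
55,1661.25,819.81,1810.19,No,1488.13,1130.65,1499.35,No,1574.69,1033.72,1596.28,No
56,1282.50,819.89,1810.11,No,1298.75,1130.90,1499.10,No,1290.63,1033.95,1596.05,No
57,1838.00,819.97,1810.03,Yes,1576.50,1131.15,1498.85,Yes,1707.25,1034.18,1595.82,Yes
58,1697.25,820.05,1809.95,No,1506.13,1131.38,1498.62,Yes,1601.69,1034.39,1595.61,Yes
59,1900.50,820.12,1809.88,Yes,1607.75,1131.61,1498.39,Yes,1754.13,1034.60,1595.40,Yes
60,1938.75,820.19,1809.81,Yes,1626.88,1131.83,1498.17,Yes,1782.81,1034.81,1595.19,Yes
61,1513.25,820.26,1809.74,No,1414.13,1132.05,1497.95,No,1463.69,1035.00,1595.00,No
62,1650.75,820.33,1809.68,No,1482.88,1132.26,1497.74,No,1566.81,1035.19,1594.81,No
63,1449.00,820.39,1809.61,No,1382.00,1132.46,1497.54,No,1415.50,1035.38,1594.62,No
64,1360.50,820.45,1809.55,No,1337.75,1132.65,1497.35,No,1349.13,1035.56,1594.44,No
65,1253.75,820.51,1809.49,No,1284.38,1132.84,1497.16,No,1269.06,1035.73,1594.27,No
66,1132.25,820.57,1809.43,No,1223.63,1133.03,1496.98,No,1177.94,1035.90,1594.10,No
67,1598.25,820.63,1809.37,No,1456.63,1133.20,1496.80,No,1527.44,1036.06,1593.94,No
68,1484.75,820.68,1809.32,No,1399.88,1133.38,1496.62,No,1442.31,1036.22,1593.78,No
69,1717.75,820.74,1809.26,No,1516.38,1133.55,1496.45,Yes,1617.06,1036.37,1593.63,Yes
70,1841.25,820.79,1809.21,Yes,1578.13,1133.71,1496.29,Yes,1709.69,1036.52,1593.48,Yes
71,1241.00,820.84,1809.16,No,1278.00,1133.87,1496.13,No,1259.50,1036.66,1593.34,No
72,1448.00,820.89,1809.11,No,1381.50,1134.02,1495.98,No,1414.75,1036.81,1593.19,No
73,1543.00,820.93,1809.07,No,1429.00,1134.18,1495.82,No,1486.00,1036.94,1593.06,No
74,1408.00,820.98,1809.02,No,1361.50,1134.32,1495.68,No,1384.75,1037.08,1592.92,No
75,1062.50,821.03,1808.97,No,1188.75,1134.47,1495.53,No,1125.63,1037.21,1592.79,No
76,1454.25,821.07,1808.93,No,1384.63,1134.61,1495.40,No,1419.44,1037.33,1592.67,No
77,1624.50,821.11,1808.89,No,1469.75,1134.74,1495.26,No,1547.13,1037.46,1592.54,No
78,1534.50,821.15,1808.85,No,1424.75,1134.87,1495.13,No,1479.63,1037.58,1592.42,No
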