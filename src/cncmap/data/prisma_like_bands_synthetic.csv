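center_nm,fwhm_nm
404.00,11.00
414.00,11.00
424.00,11.00
434.00,11.00
444.00,11.00
454.00,11.00
464.00,11.00
472.00,11.00
478.32,11.00
484.64,11.00
490.96,11.00
497.28,11.00
503.59,11.00
509.91,11.00
516.23,11.00
522.55,11.00
528.87,11.00
535.19,11.00
541.51,11.00
547.83,11.00
554.14,11.00
560.46,11.00
566.78,11.00
573.10,11.00
579.42,11.00
585.74,11.00
592.06,11.00
598.38,11.00
604.70,11.00
611.01,11.00
617.33,11.00
623.65,11.00
629.97,11.00
636.29,11.00
642.61,11.00
648.93,11.00
655.25,11.00
661.57,11.00
667.88,11.00
674.20,11.00
680.52,11.00
686.84,11.00
693.16,11.00
699.48,11.00
705.80,11.00
712.12,11.00
718.43,11.00
724.75,11.00
731.07,11.00
737.39,11.00
743.71,11.00
750.03,11.00
756.35,11.00
762.67,11.00
768.99,11.00
775.30,11.00
781.62,11.00
787.94,11.00
794.26,11.00
800.58,11.00
806.90,11.00
813.22,11.00
819.54,11.00
825.86,11.00
832.17,11.00
838.49,11.00
844.81,11.00
851.13,11.00
857.45,11.00
863.77,11.00
870.09,11.00
876.41,11.00
882.72,11.00
889.04,11.00
895.36,11.00
901.68,11.00
908.00,11.00
914.32,11.00
920.64,11.00
926.96,11.00
933.28,11.00
939.59,11.00
945.91,11.00
952.23,11.00
958.55,11.00
964.87,11.00
971.19,11.00
977.51,11.00
983.83,11.00
990.14,11.00
996.46,11.00
1002.78,11.00
1009.10,11.00
1015.42,11.00
1021.74,11.00
1028.06,11.00
1034.38,11.00
1040.70,11.00
1047.01,11.00
1053.33,11.00
1059.65,11.00
1065.97,11.00
1072.29,11.00
1078.61,11.00
1084.93,11.00
1091.25,11.00
1097.57,11.00
1103.88,11.00
1110.20,11.00
1116.52,11.00
1122.84,11.00
1129.16,11.00
1135.48,11.00
1141.80,11.00
1148.12,11.00
1154.43,11.00
1160.75,11.00
1167.07,11.00
1173.39,11.00
1179.71,11.00
1186.03,11.00
1192.35,11.00
1198.67,11.00
1204.99,11.00
1211.30,11.00
1217.62,11.00
1223.94,11.00
1230.26,11.00
1236.58,11.00
1242.90,11.00
1249.22,11.00
1255.54,11.00
1261.86,11.00
1268.17,11.00
1274.49,11.00
1280.81,11.00
1287.13,11.00
1293.45,11.00
1299.77,11.00
1306.09,11.00
1312.41,11.00
1318.72,11.00
1325.04,11.00
1331.36,11.00
1337.68,11.00
1344.00,11.00
1352.00,28.00
1377.00,28.00
1402.00,28.00
1427.00,28.00
1452.00,28.00
1477.00,28.00
1502.00,28.00
1515.00,11.00
1521.32,11.00
1527.64,11.00
1533.95,11.00
1540.27,11.00
1546.59,11.00
1552.91,11.00
1559.23,11.00
1565.55,11.00
1571.86,11.00
1578.18,11.00
1584.50,11.00
1590.82,11.00
1597.14,11.00
1603.45,11.00
1609.77,11.00
1616.09,11.00
1622.41,11.00
1628.73,11.00
1635.05,11.00
1641.36,11.00
1647.68,11.00
1654.00,11.00
1660.32,11.00
1666.64,11.00
1672.95,11.00
1679.27,11.00
1685.59,11.00
1691.91,11.00
1698.23,11.00
1704.55,11.00
1710.86,11.00
1717.18,11.00
1723.50,11.00
1729.82,11.00
1736.14,11.00
1742.45,11.00
1748.77,11.00
1755.09,11.00
1761.41,11.00
1767.73,11.00
1774.05,11.00
1780.36,11.00
1786.68,11.00
1793.00,11.00
1802.00,28.00
1827.00,28.00
1852.00,28.00
1877.00,28.00
1902.00,28.00
1927.00,28.00
1952.00,28.00
1977.00,28.00
2004.00,11.00
2010.27,11.00
2016.55,11.00
2022.82,11.00
2029.09,11.00
2035.36,11.00
2041.64,11.00
2047.91,11.00
2054.18,11.00
2060.45,11.00
2066.73,11.00
2073.00,11.00
2079.27,11.00
2085.55,11.00
2091.82,11.00
2098.09,11.00
2104.36,11.00
2110.64,11.00
2116.91,11.00
2123.18,11.00
2129.45,11.00
2135.73,11.00
2142.00,11.00
2160.00,38.00
2195.00,38.00
2230.00,38.00
2265.00,38.00
2300.00,38.00
2335.00,38.00
2370.00,38.00
2405.00,38.00
2440.00,38.00
2475.00,38.00
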