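Toxin	ANF-A	ANF-J	BR-A	BR-J	CAL-A	CAL-J	ENP-A	ENP-J	LSG-A	LSG-J
3FTx-1	4.9	34.3	0.0	0.0	0.0	0.0	31.8	72.8	208.0	0.0
3FTx-2	1.3	26.4	0.0	0.0	55.9	0.0	2.3	14.8	126.9	0.0
BPP-1	53071.6	158.1	86213.5	187.4	128985.6	286.2	159027.1	38210.4	13477.2	537.4
CRISP-1	4212.4	1816.6	7813.9	1048.2	12682.6	2585.5	5019.5	737.7	2913.9	831.4
CTL-1	51386.2	63742.6	53616.6	89233.9	95086.4	97080.1	59762.9	112292.5	52000.6	94736.0
CTL-2	12441.0	7908.6	11010.3	20293.1	17034.3	25689.6	19719.6	32860.3	10156.3	22073.0
CTL-3	973.8	1078.3	737.2	3454.1	1442.6	2686.4	1753.7	2887.8	1350.7	1658.6
CTL-4	5678.0	6356.9	6869.3	10195.6	7813.3	13458.5	9118.3	12686.1	5080.9	10072.9
CTL-5	9954.2	7948.3	10814.6	18836.6	16923.9	29450.0	17300.5	34528.5	10705.3	18995.7
CTL-6	25421.9	25037.9	30921.3	24830.3	48102.2	26066.8	51036.2	45545.9	28498.6	21708.6
CTL-7	964.9	2048.7	385.9	4328.4	1273.5	2866.0	1189.7	2679.1	1346.6	2615.7
CTL-8	46187.0	52315.6	37463.5	84319.7	87363.6	81965.5	53409.5	93030.7	46803.0	83239.0
CTL-9	2198.3	3429.7	4724.3	6745.3	6765.7	8127.2	3788.2	7211.4	3195.4	5055.0
CTL-10	27089.7	35138.3	36287.6	26398.0	52737.4	22516.0	45983.0	54230.4	33430.3	21842.3
CTL-11	50.7	80.9	47.1	116.7	88.3	3465.0	38.7	140.6	45.0	150.7
CTL-12	0.7	4.7	0.0	0.0	0.0	0.0	7.0	26.1	37.1	0.3
CTL-13	13.8	85.8	0.6	6.1	2.6	315.5	10.9	26.2	11.9	12.1
HYAL-1	43.3	177.6	457.7	421.9	535.3	146.5	384.4	508.5	93.5	290.7
KUN-1	284.9	77.3	189.9	168.0	261.6	250.1	462.4	346.3	91.8	98.7
KUN-2	20.8	9.8	17.6	18.0	26.6	58.5	37.6	30.6	9.3	8.8
LAAO-1	4212.0	2024.9	12398.7	3905.8	7273.1	217.8	14383.4	27405.7	7619.6	4373.3
MYO-1	345599.5	584312.9	362582.0	383003.8	85226.1	445793.6	104366.4	367.4	528354.5	491846.2
MYO-2	39894.7	57390.3	120236.3	52970.6	57.5	45995.1	45.3	64.4	62678.4	44084.5
NGF-1	934.6	14.9	1303.3	17.6	1366.3	1.1	1714.4	199.9	334.1	15.5
NUC-1	584.3	568.8	952.9	968.4	1334.4	1343.3	879.9	1372.4	538.0	736.3
PDE-1	267.6	326.4	616.0	451.3	741.1	2394.6	442.1	989.5	157.5	353.5
PLA2-1	73635.0	50512.0	19913.5	129007.9	23642.6	87609.4	101745.6	168921.5	22293.7	69631.6
PLA2-2	419.7	18.1	1070.0	175.8	2103.7	4.8	643.1	253.3	1316.8	25.0
PLB-1	1169.8	200.1	1780.1	890.1	1703.4	183.2	2057.8	1341.6	930.6	825.9
SVMPII-1	2935.9	16.8	894.7	26.4	8961.3	28.5	2417.1	2287.5	4.6	12.5
SVMPII-2	14706.7	11144.9	9131.7	13628.9	20869.0	18161.1	9169.5	45877.7	8186.0	11976.5
SVMPII-3	8403.7	85.8	13420.9	122.9	19674.9	96.0	3859.9	8678.2	7624.9	96.1
SVMPII-4	4049.2	32884.1	33.6	26825.5	465.2	40080.3	1069.5	65273.7	76.8	23508.1
SVMPII-5	133.8	1.4	130.5	31.7	243.8	52.5	274.1	245.0	58.8	8.9
SVMPIII-1	10470.4	20.3	4165.3	38.5	13005.4	19.6	3558.5	3192.1	1649.2	36.0
SVMPIII-2	81.8	1020.4	10.8	1331.2	34.1	1841.7	30.7	3354.8	2.9	717.6
SVMPIII-3	1101.1	655.4	1571.5	1644.6	3125.8	575.7	2258.2	3107.0	897.0	1277.2
SVMPIII-4	1967.6	14665.0	3276.2	14444.0	4069.7	8979.9	1126.3	8554.7	1692.6	21122.7
SVMPIII-5	11432.5	14.8	37376.4	50.4	66467.1	21.6	5538.5	21270.8	12774.1	30.7
SVMPIII-6	1049.4	5.8	1440.1	33.7	7217.5	14.0	959.9	149.0	958.6	26.8
SVMPIII-7	1589.1	39.4	2898.5	552.5	4591.6	47.6	1483.7	3986.9	1562.0	136.6
SVMPIII-8	7083.7	7270.7	15148.7	10705.2	23978.5	7246.1	5059.9	26521.8	5618.1	11705.0
SVMPIII-9	410.8	698.9	69.3	135.8	164.4	771.5	142.2	162.0	53.0	156.2
SVMPIII-10	1904.7	1570.5	2132.2	3537.7	3682.4	1198.9	1430.1	1808.5	1822.8	3109.8
SVSP-1	3212.0	198.3	984.0	3888.3	4673.2	1224.2	8141.1	4747.8	1234.5	692.6
SVSP-2	59597.7	13741.0	15149.6	21203.4	23261.7	5467.9	24211.7	21053.0	23635.2	15030.7
SVSP-3	28867.7	2698.0	12881.5	8499.8	14023.4	2218.3	14985.7	5532.7	17129.3	2682.5
SVSP-4	4928.5	709.0	2538.4	4983.4	11701.6	1970.9	24651.4	18537.7	2679.1	937.2
SVSP-5	10108.4	1331.1	5963.2	7293.7	12403.7	1500.3	28764.4	26790.9	2859.5	1464.5
SVSP-6	23404.3	88.6	22095.4	4622.9	69975.9	360.9	100840.6	60273.2	18518.5	103.2
SVSP-7	991.9	14.8	366.8	391.9	1366.8	46.9	548.2	176.6	829.0	1.9
SVSP-8	204.9	4.7	73.5	61.7	261.3	0.0	556.6	163.3	85.9	1.9
SVSP-9	15110.9	5.0	4493.4	1668.1	52151.0	21.3	78083.6	14284.9	4042.9	8.6
SVSP-10	72896.1	5954.9	32324.0	7854.4	23067.6	3146.0	10182.4	3416.3	48775.3	8161.3
SVSP-11	2968.0	60.1	753.0	1519.2	4619.7	119.6	8866.7	2901.5	821.3	113.4
SVSP-12	1016.0	45.9	454.1	234.7	1074.5	19.0	2670.4	1587.9	463.4	66.2
VEGF-1	568.0	568.9	330.7	1331.7	1383.6	2524.5	1759.7	2668.9	376.9	279.5
VEGF-2	59.2	28.5	97.6	115.6	317.6	70.6	292.6	364.4	31.8	34.9
Vespryn-1	2029.5	1612.2	1371.0	1230.1	2538.4	1618.2	2705.7	4048.9	1730.7	682.9
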