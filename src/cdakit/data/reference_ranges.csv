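kv,mas,step,bound,mean,sd,n
50,1.2,1,Min,880.6,129.0,9
50,1.2,2,Min,1173.9,143.5,9
50,1.2,3,Min,1417.8,147.2,9
50,1.2,4,Min,1614.4,155.8,9
50,1.2,5,Min,1826.1,142.2,9
50,1.2,6,Min,1985.0,109.0,9
50,1.2,7,Min,2157.2,104.0,9
50,1.2,8,Min,2318.9,60.1,9
50,1.2,9,Min,2447.2,56.8,9
50,1.2,10,Min,2478.3,90.8,9
50,1.2,1,Max,1130.6,69.6,9
50,1.2,2,Max,1367.8,122.3,9
50,1.2,3,Max,1590.8,70.8,9
50,1.2,4,Max,1841.7,112.4,9
50,1.2,5,Max,1982.8,93.9,9
50,1.2,6,Max,2182.8,99.7,9
50,1.2,7,Max,2379.4,111.4,9
50,1.2,8,Max,2470.6,126.5,9
50,1.2,9,Max,2588.9,116.2,9
50,1.2,10,Max,2798.9,47.4,9
60,1.2,1,Min,672.8,142.5,9
60,1.2,2,Min,928.9,155.9,9
60,1.2,3,Min,1194.4,154.6,9
60,1.2,4,Min,1423.9,163.3,9
60,1.2,5,Min,1658.9,157.7,9
60,1.2,6,Min,1848.3,158.0,9
60,1.2,7,Min,2012.8,157.7,9
60,1.2,8,Min,2149.4,139.6,9
60,1.2,9,Min,2280.6,129.0,9
60,1.2,10,Min,2363.3,96.8,9
60,1.2,1,Max,919.4,88.3,9
60,1.2,2,Max,1191.7,122.1,9
60,1.2,3,Max,1446.7,103.9,9
60,1.2,4,Max,1659.4,112.8,9
60,1.2,5,Max,1821.1,115.0,9
60,1.2,6,Max,2018.9,104.8,9
60,1.2,7,Max,2181.1,142.7,9
60,1.2,8,Max,2268.3,107.1,9
60,1.2,9,Max,2381.1,143.7,9
60,1.2,10,Max,2539.4,94.0,9
60,12,1,Min,-330.0,104.1,9
60,12,2,Min,63.3,170.8,9
60,12,3,Min,465.0,148.5,9
60,12,4,Min,837.8,137.7,9
60,12,5,Min,1125.6,116.9,9
60,12,6,Min,1291.9,195.1,9
60,12,7,Min,1554.4,133.8,9
60,12,8,Min,1741.1,149.6,9
60,12,9,Min,1965.6,159.1,9
60,12,10,Min,2156.7,166.1,9
60,12,1,Max,-148.6,68.3,9
60,12,2,Max,231.1,120.4,9
60,12,3,Max,747.8,119.7,9
60,12,4,Max,1078.9,150.4,9
60,12,5,Max,1365.0,115.1,9
60,12,6,Max,1507.2,156.3,9
60,12,7,Max,1727.2,158.9,9
60,12,8,Max,1910.0,142.2,9
60,12,9,Max,2115.0,156.3,9
60,12,10,Max,2306.7,143.2,9
70,1.2,1,Min,86.1,52.2,9
70,1.2,2,Min,294.7,78.7,9
70,1.2,3,Min,546.7,78.8,9
70,1.2,4,Min,732.9,81.9,9
70,1.2,5,Min,871.1,80.5,9
70,1.2,6,Min,976.7,148.1,9
70,1.2,7,Min,1255.6,122.5,9
70,1.2,8,Min,1379.4,187.2,9
70,1.2,9,Min,1590.6,240.1,9
70,1.2,10,Min,1815.0,212.1,9
70,1.2,1,Max,302.8,120.2,9
70,1.2,2,Max,490.0,128.7,9
70,1.2,3,Max,762.8,82.4,9
70,1.2,4,Max,885.0,80.2,9
70,1.2,5,Max,1045.6,183.3,9
70,1.2,6,Max,1161.1,189.9,9
70,1.2,7,Max,1342.8,196.3,9
70,1.2,8,Max,1570.0,235.9,9
70,1.2,9,Max,1760.6,207.5,9
70,1.2,10,Max,2007.2,196.1,9
80,1.2,1,Min,-103.3,133.6,9
80,1.2,2,Min,140.6,83.1,9
80,1.2,3,Min,328.3,95.9,9
80,1.2,4,Min,513.3,102.6,9
80,1.2,5,Min,682.2,83.8,9
80,1.2,6,Min,797.2,115.3,9
80,1.2,7,Min,960.0,156.9,9
80,1.2,8,Min,1177.8,119.3,9
80,1.2,9,Min,1380.0,177.3,9
80,1.2,10,Min,1608.9,165.9,9
80,1.2,1,Max,92.2,135.9,9
80,1.2,2,Max,359.4,121.1,9
80,1.2,3,Max,487.8,178.1,9
80,1.2,4,Max,663.9,117.6,9
80,1.2,5,Max,850.6,130.9,9
80,1.2,6,Max,975.6,179.3,9
80,1.2,7,Max,1142.2,135.2,9
80,1.2,8,Max,1339.4,201.2,9
80,1.2,9,Max,1563.9,185.7,9
80,1.2,10,Max,1786.7,162.3,9
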