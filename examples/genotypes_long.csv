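Sample,Marker,Allele,Height,Size
EX-01,D3S1358,5,70.42765511123817,83.0
EX-01,D3S1358,6,132.8167739267596,87.0
EX-01,D3S1358,7,2922.449850503942,91.0
EX-01,D3S1358,8,130.1652216905499,95.0
EX-01,vWA,13,454.4857606491391,152.0
EX-01,vWA,14,6550.865493243196,156.0
EX-01,vWA,15,66.49413070569258,160.0
EX-01,D16S539,11,137.78567619341916,256.0
EX-01,D16S539,12,1569.1898578619716,260.0
EX-01,D16S539,13,13901.98781830048,264.0
EX-01,D16S539,14,5489.700797106732,268.0
EX-01,D16S539,15,186.2204352320555,272.0
EX-01,CSF1PO,8,130.78389190887466,309.0
EX-01,CSF1PO,9,2815.8516728618847,313.0
EX-01,CSF1PO,10,211.17580078838853,317.0
EX-01,CSF1PO,11,1386.917588171294,321.0
EX-01,CSF1PO,12,3897.3666062429534,325.0
EX-01,CSF1PO,13,30000.0,329.0
EX-01,CSF1PO,14,2044.1736633044623,333.0
EX-01,TPOX,11,122.48984195691013,353.0
EX-01,TPOX,12,405.9700132434655,357.0
EX-01,TPOX,13,3691.680749762291,361.0
EX-01,TPOX,14,3011.8452443272813,365.0
EX-01,TPOX,15,66.27978305554925,369.0
EX-01,D8S1179,8,105.80321889545584,199.0
EX-01,D8S1179,9,1639.348828401746,203.0
EX-01,D8S1179,13,66.80279782411465,219.0
EX-01,D8S1179,14,552.1245877413436,223.0
EX-01,D21S11,10,110.47469141637882,125.0
EX-01,D21S11,11,254.0048887339546,129.0
EX-01,D21S11,12,3329.597754396447,133.0
EX-01,D21S11,15,1199.6257920974674,145.0
EX-01,D21S11,16,8960.948364473095,149.0
EX-01,D21S11,17,351.76564247278867,153.0
EX-01,D18S51,12,165.70251167490719,245.0
EX-01,D18S51,13,858.3318734101746,249.0
EX-01,D18S51,14,9944.396422049476,253.0
EX-01,D18S51,15,8885.326645217929,257.0
EX-01,D18S51,16,30000.0,261.0
EX-01,D18S51,17,1807.5354714096377,265.0
EX-01,D2S441,10,783.796644219334,168.0
EX-01,D2S441,11,54.07351946413798,172.0
EX-01,D2S441,12,1912.7347706044702,176.0
EX-01,D2S441,13,20278.871220203946,180.0
EX-01,D2S441,14,627.4291619354972,184.0
EX-01,D19S433,8,174.4841713710287,78.0
EX-01,D19S433,9,5239.645777998373,82.0
EX-01,D19S433,10,136.15368699522796,86.0
EX-01,D19S433,11,110.64544357175365,90.0
EX-01,D19S433,12,456.0002431071738,94.0
EX-01,D19S433,13,7288.246597241442,98.0
EX-01,D19S433,14,207.2808192981393,102.0
EX-01,TH01,5,2336.9383812148444,165.0
EX-01,TH01,6,5120.769186832413,169.0
EX-01,TH01,7,30000.0,173.0
EX-01,TH01,8,3709.0209013340623,177.0
EX-01,FGA,13,209.19274310436649,180.0
EX-01,FGA,14,1576.339911368539,184.0
EX-01,FGA,15,61.194289803724914,188.0
EX-01,D22S1045,11,130.7334357399264,88.0
EX-01,D22S1045,12,1365.8668686810793,91.0
EX-01,D22S1045,13,455.8209802130235,94.0
EX-01,D22S1045,14,3131.3176302613183,97.0
EX-01,D22S1045,15,175.1006293833881,100.0
EX-01,D5S818,9,527.6069585477765,126.0
EX-01,D5S818,10,7986.830207427848,130.0
EX-01,D5S818,11,219.5479592652045,134.0
EX-01,D13S317,9,718.9807880082559,208.0
EX-01,D13S317,11,279.81660036330015,216.0
EX-01,D13S317,12,629.0512636575611,220.0
EX-01,D13S317,13,6911.751118015481,224.0
EX-01,D13S317,14,492.4124035034184,228.0
EX-01,D7S820,12,51.27404068365453,269.0
EX-01,D7S820,13,253.26389277641317,273.0
EX-01,D7S820,14,3027.517491018335,277.0
EX-01,D7S820,15,6001.956964548243,281.0
EX-01,D7S820,16,208.91939438400664,285.0
EX-01,SE33,14,1249.33582314853,290.0
EX-01,SE33,15,9808.341293630903,294.0
EX-01,SE33,16,625.6678845892133,298.0
EX-01,SE33,17,3329.5672544717154,302.0
EX-01,SE33,18,153.8186049033642,306.0
EX-01,D10S1248,15,62.577078902299306,102.0
EX-01,D10S1248,16,1155.6415929093353,106.0
EX-01,D10S1248,17,8628.23399986981,110.0
EX-01,D10S1248,18,288.72338980010005,114.0
EX-01,D1S1656,9,60.49531779793978,151.0
EX-01,D1S1656,10,1351.109606842383,155.0
EX-01,D12S391,6,118.00498207612958,166.0
EX-01,D12S391,7,100.50586713503175,170.0
EX-01,D12S391,8,6604.859768051637,174.0
EX-01,D12S391,9,75.5400003460298,178.0
EX-01,D12S391,10,140.72249139117767,182.0
EX-01,D2S1338,11,1593.3433025450224,264.0
EX-01,D2S1338,12,19865.14406951884,268.0
EX-01,D2S1338,13,915.844332447459,272.0
EX-02,D3S1358,8,744.5469128805868,95.0
EX-02,D3S1358,9,47.80578317698278,99.0
EX-02,D3S1358,11,306.49060982058637,107.0
EX-02,D3S1358,12,3122.587139367939,111.0
EX-02,D3S1358,13,136.62876209414353,115.0
EX-02,vWA,11,269.91352173859184,144.0
EX-02,vWA,12,2309.5370649623546,148.0
EX-02,vWA,13,53.57537808782729,152.0
EX-02,D16S539,12,1874.6821224539033,260.0
EX-02,D16S539,13,17031.894653451374,264.0
EX-02,CSF1PO,7,53.8820607386323,305.0
EX-02,CSF1PO,8,1056.3005198654303,309.0
EX-02,CSF1PO,11,113.10187446035444,321.0
EX-02,CSF1PO,12,405.4150362895775,325.0
EX-02,CSF1PO,13,2795.221976329337,329.0
EX-02,CSF1PO,14,165.64423409451788,333.0
EX-02,TPOX,9,131.82577562389736,345.0
EX-02,TPOX,11,76.99288264526501,353.0
EX-02,D8S1179,6,134.28201705186615,191.0
EX-02,D8S1179,7,1112.689754473111,195.0
EX-02,D8S1179,8,26698.970254918877,199.0
EX-02,D8S1179,9,508.60149406085077,203.0
EX-02,D21S11,11,60.871903956124356,129.0
EX-02,D21S11,12,143.9847969595954,133.0
EX-02,D21S11,13,2570.973981318736,137.0
EX-02,D21S11,14,1247.7364145426197,141.0
EX-02,D21S11,15,57.52834273613421,145.0
EX-02,D18S51,10,2896.9218558880107,237.0
EX-02,D18S51,11,25882.787913886546,241.0
EX-02,D18S51,12,763.651602001777,245.0
EX-02,D2S441,10,197.36230025241608,168.0
EX-02,D2S441,11,337.6982012965613,172.0
EX-02,D2S441,12,3958.8160991059167,176.0
EX-02,D2S441,13,92.02141503982466,180.0
EX-02,TH01,6,139.2073149488885,169.0
EX-02,TH01,7,1821.9498387693113,173.0
EX-02,TH01,8,30000.0,177.0
EX-02,TH01,9,1658.6890146241312,181.0
EX-02,FGA,11,85.86140461803431,172.0
EX-02,FGA,12,1321.0183036465148,176.0
EX-02,FGA,13,3646.240446555286,180.0
EX-02,FGA,14,29476.843933754524,184.0
EX-02,FGA,15,1693.6465838816162,188.0
EX-02,D22S1045,11,129.69270026229185,88.0
EX-02,D22S1045,12,2207.579472690143,91.0
EX-02,D22S1045,13,11550.023048228084,94.0
EX-02,D22S1045,14,402.76505413310673,97.0
EX-02,D5S818,13,935.3224758418384,142.0
EX-02,D5S818,14,9710.660583161358,146.0
EX-02,D5S818,15,451.9688694245043,150.0
EX-02,D13S317,10,184.50169953931942,212.0
EX-02,D13S317,12,2213.324412271314,220.0
EX-02,D13S317,13,4240.018146721805,224.0
EX-02,D13S317,14,30000.0,228.0
EX-02,D13S317,15,1867.0785380429859,232.0
EX-02,D7S820,13,1196.391743760291,273.0
EX-02,D7S820,14,11041.664741889581,277.0
EX-02,D7S820,15,544.25834988556,281.0
EX-02,SE33,11,334.2910805355809,278.0
EX-02,D10S1248,10,2438.332939712145,82.0
EX-02,D10S1248,11,19461.304377282304,86.0
EX-02,D10S1248,12,23569.65427329571,90.0
EX-02,D10S1248,13,1044.4101167006936,94.0
EX-02,D1S1656,8,675.194205290549,147.0
EX-02,D1S1656,9,670.2237844551707,151.0
EX-02,D1S1656,10,19036.967248960143,155.0
EX-02,D1S1656,11,836.3375283383522,159.0
EX-02,D12S391,11,719.8467760412291,186.0
EX-02,D12S391,12,10172.642047267838,190.0
EX-02,D12S391,13,393.971936078477,194.0
EX-02,D2S1338,12,262.5035258377346,268.0
EX-02,D2S1338,13,2224.33908272449,272.0
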