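Sample Name,Marker,Allele 1,Allele 2,Allele 3,Allele 4,Allele 5,Allele 6,Allele 7,Height 1,Height 2,Height 3,Height 4,Height 5,Height 6,Height 7,Size 1,Size 2,Size 3,Size 4,Size 5,Size 6,Size 7
EX-01,D3S1358,5,6,7,8,,,,70.42765511123817,132.8167739267596,2922.449850503942,130.1652216905499,,,,83.0,87.0,91.0,95.0,,,
EX-01,vWA,13,14,15,,,,,454.4857606491391,6550.865493243196,66.49413070569258,,,,,152.0,156.0,160.0,,,,
EX-01,D16S539,11,12,13,14,15,,,137.78567619341916,1569.1898578619716,13901.98781830048,5489.700797106732,186.2204352320555,,,256.0,260.0,264.0,268.0,272.0,,
EX-01,CSF1PO,8,9,10,11,12,13,14,130.78389190887466,2815.8516728618847,211.17580078838853,1386.917588171294,3897.3666062429534,30000.0,2044.1736633044623,309.0,313.0,317.0,321.0,325.0,329.0,333.0
EX-01,TPOX,11,12,13,14,15,,,122.48984195691013,405.9700132434655,3691.680749762291,3011.8452443272813,66.27978305554925,,,353.0,357.0,361.0,365.0,369.0,,
EX-01,D8S1179,8,9,13,14,,,,105.80321889545584,1639.348828401746,66.80279782411465,552.1245877413436,,,,199.0,203.0,219.0,223.0,,,
EX-01,D21S11,10,11,12,15,16,17,,110.47469141637882,254.0048887339546,3329.597754396447,1199.6257920974674,8960.948364473095,351.76564247278867,,125.0,129.0,133.0,145.0,149.0,153.0,
EX-01,D18S51,12,13,14,15,16,17,,165.70251167490719,858.3318734101746,9944.396422049476,8885.326645217929,30000.0,1807.5354714096377,,245.0,249.0,253.0,257.0,261.0,265.0,
EX-01,D2S441,10,11,12,13,14,,,783.796644219334,54.07351946413798,1912.7347706044702,20278.871220203946,627.4291619354972,,,168.0,172.0,176.0,180.0,184.0,,
EX-01,D19S433,8,9,10,11,12,13,14,174.4841713710287,5239.645777998373,136.15368699522796,110.64544357175365,456.0002431071738,7288.246597241442,207.2808192981393,78.0,82.0,86.0,90.0,94.0,98.0,102.0
EX-01,TH01,5,6,7,8,,,,2336.9383812148444,5120.769186832413,30000.0,3709.0209013340623,,,,165.0,169.0,173.0,177.0,,,
EX-01,FGA,13,14,15,,,,,209.19274310436649,1576.339911368539,61.194289803724914,,,,,180.0,184.0,188.0,,,,
EX-01,D22S1045,11,12,13,14,15,,,130.7334357399264,1365.8668686810793,455.8209802130235,3131.3176302613183,175.1006293833881,,,88.0,91.0,94.0,97.0,100.0,,
EX-01,D5S818,9,10,11,,,,,527.6069585477765,7986.830207427848,219.5479592652045,,,,,126.0,130.0,134.0,,,,
EX-01,D13S317,9,11,12,13,14,,,718.9807880082559,279.81660036330015,629.0512636575611,6911.751118015481,492.4124035034184,,,208.0,216.0,220.0,224.0,228.0,,
EX-01,D7S820,12,13,14,15,16,,,51.27404068365453,253.26389277641317,3027.517491018335,6001.956964548243,208.91939438400664,,,269.0,273.0,277.0,281.0,285.0,,
EX-01,SE33,14,15,16,17,18,,,1249.33582314853,9808.341293630903,625.6678845892133,3329.5672544717154,153.8186049033642,,,290.0,294.0,298.0,302.0,306.0,,
EX-01,D10S1248,15,16,17,18,,,,62.577078902299306,1155.6415929093353,8628.23399986981,288.72338980010005,,,,102.0,106.0,110.0,114.0,,,
EX-01,D1S1656,9,10,,,,,,60.49531779793978,1351.109606842383,,,,,,151.0,155.0,,,,,
EX-01,D12S391,6,7,8,9,10,,,118.00498207612958,100.50586713503175,6604.859768051637,75.5400003460298,140.72249139117767,,,166.0,170.0,174.0,178.0,182.0,,
EX-01,D2S1338,11,12,13,,,,,1593.3433025450224,19865.14406951884,915.844332447459,,,,,264.0,268.0,272.0,,,,
EX-02,D3S1358,8,9,11,12,13,,,744.5469128805868,47.80578317698278,306.49060982058637,3122.587139367939,136.62876209414353,,,95.0,99.0,107.0,111.0,115.0,,
EX-02,vWA,11,12,13,,,,,269.91352173859184,2309.5370649623546,53.57537808782729,,,,,144.0,148.0,152.0,,,,
EX-02,D16S539,12,13,,,,,,1874.6821224539033,17031.894653451374,,,,,,260.0,264.0,,,,,
EX-02,CSF1PO,7,8,11,12,13,14,,53.8820607386323,1056.3005198654303,113.10187446035444,405.4150362895775,2795.221976329337,165.64423409451788,,305.0,309.0,321.0,325.0,329.0,333.0,
EX-02,TPOX,9,11,,,,,,131.82577562389736,76.99288264526501,,,,,,345.0,353.0,,,,,
EX-02,D8S1179,6,7,8,9,,,,134.28201705186615,1112.689754473111,26698.970254918877,508.60149406085077,,,,191.0,195.0,199.0,203.0,,,
EX-02,D21S11,11,12,13,14,15,,,60.871903956124356,143.9847969595954,2570.973981318736,1247.7364145426197,57.52834273613421,,,129.0,133.0,137.0,141.0,145.0,,
EX-02,D18S51,10,11,12,,,,,2896.9218558880107,25882.787913886546,763.651602001777,,,,,237.0,241.0,245.0,,,,
EX-02,D2S441,10,11,12,13,,,,197.36230025241608,337.6982012965613,3958.8160991059167,92.02141503982466,,,,168.0,172.0,176.0,180.0,,,
EX-02,D19S433,,,,,,,,,,,,,,,,,,,,,
EX-02,TH01,6,7,8,9,,,,139.2073149488885,1821.9498387693113,30000.0,1658.6890146241312,,,,169.0,173.0,177.0,181.0,,,
EX-02,FGA,11,12,13,14,15,,,85.86140461803431,1321.0183036465148,3646.240446555286,29476.843933754524,1693.6465838816162,,,172.0,176.0,180.0,184.0,188.0,,
EX-02,D22S1045,11,12,13,14,,,,129.69270026229185,2207.579472690143,11550.023048228084,402.76505413310673,,,,88.0,91.0,94.0,97.0,,,
EX-02,D5S818,13,14,15,,,,,935.3224758418384,9710.660583161358,451.9688694245043,,,,,142.0,146.0,150.0,,,,
EX-02,D13S317,10,12,13,14,15,,,184.50169953931942,2213.324412271314,4240.018146721805,30000.0,1867.0785380429859,,,212.0,220.0,224.0,228.0,232.0,,
EX-02,D7S820,13,14,15,,,,,1196.391743760291,11041.664741889581,544.25834988556,,,,,273.0,277.0,281.0,,,,
EX-02,SE33,11,,,,,,,334.2910805355809,,,,,,,278.0,,,,,,
EX-02,D10S1248,10,11,12,13,,,,2438.332939712145,19461.304377282304,23569.65427329571,1044.4101167006936,,,,82.0,86.0,90.0,94.0,,,
EX-02,D1S1656,8,9,10,11,,,,675.194205290549,670.2237844551707,19036.967248960143,836.3375283383522,,,,147.0,151.0,155.0,159.0,,,
EX-02,D12S391,11,12,13,,,,,719.8467760412291,10172.642047267838,393.971936078477,,,,,186.0,190.0,194.0,,,,
EX-02,D2S1338,12,13,,,,,,262.5035258377346,2224.33908272449,,,,,,268.0,272.0,,,,,
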