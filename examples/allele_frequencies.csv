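Locus,Allele,Frequency
D3S1358,6,0.07894
D3S1358,7,0.16941
D3S1358,8,0.22267
D3S1358,9,0.13617
D3S1358,10,0.17115
D3S1358,11,0.10785
D3S1358,12,0.06888
D3S1358,13,0.04493
vWA,9,0.07626
vWA,10,0.09257
vWA,11,0.06334
vWA,12,0.19088
vWA,13,0.16681
vWA,14,0.26792
vWA,15,0.0707
vWA,16,0.07152
D16S539,11,0.06818
D16S539,12,0.20587
D16S539,13,0.1117
D16S539,14,0.17508
D16S539,15,0.2002
D16S539,16,0.06707
D16S539,17,0.12337
D16S539,18,0.04853
CSF1PO,8,0.08099
CSF1PO,9,0.20002
CSF1PO,10,0.08284
CSF1PO,11,0.11375
CSF1PO,12,0.10156
CSF1PO,13,0.10942
CSF1PO,14,0.15873
CSF1PO,15,0.15269
TPOX,8,0.04007
TPOX,9,0.0652
TPOX,10,0.07334
TPOX,11,0.25469
TPOX,12,0.17106
TPOX,13,0.22733
TPOX,14,0.11177
TPOX,15,0.05654
D8S1179,7,0.10229
D8S1179,8,0.07982
D8S1179,9,0.16108
D8S1179,10,0.34492
D8S1179,11,0.07976
D8S1179,12,0.07415
D8S1179,13,0.09669
D8S1179,14,0.06129
D21S11,11,0.06543
D21S11,12,0.12456
D21S11,13,0.11705
D21S11,14,0.17032
D21S11,15,0.18846
D21S11,16,0.14974
D21S11,17,0.09162
D21S11,18,0.09282
D18S51,10,0.14941
D18S51,11,0.04518
D18S51,12,0.12881
D18S51,13,0.09514
D18S51,14,0.27308
D18S51,15,0.18022
D18S51,16,0.09635
D18S51,17,0.03181
D2S441,8,0.06052
D2S441,9,0.18081
D2S441,10,0.1082
D2S441,11,0.12383
D2S441,12,0.17618
D2S441,13,0.20866
D2S441,14,0.10113
D2S441,15,0.04067
D19S433,7,0.07641
D19S433,8,0.09042
D19S433,9,0.17478
D19S433,10,0.16742
D19S433,11,0.08905
D19S433,12,0.11393
D19S433,13,0.19891
D19S433,14,0.08908
TH01,6,0.04812
TH01,7,0.11621
TH01,8,0.23108
TH01,9,0.14904
TH01,10,0.09503
TH01,11,0.19088
TH01,12,0.05576
TH01,13,0.11388
FGA,11,0.0671
FGA,12,0.15566
FGA,13,0.06565
FGA,14,0.21148
FGA,15,0.15231
FGA,16,0.24717
FGA,17,0.08391
FGA,18,0.01672
D22S1045,9,0.01898
D22S1045,10,0.06217
D22S1045,11,0.11561
D22S1045,12,0.15257
D22S1045,13,0.4233
D22S1045,14,0.10528
D22S1045,15,0.07476
D22S1045,16,0.04733
D5S818,8,0.02304
D5S818,9,0.05955
D5S818,10,0.16004
D5S818,11,0.13203
D5S818,12,0.25585
D5S818,13,0.1616
D5S818,14,0.08357
D5S818,15,0.12432
D13S317,8,0.05119
D13S317,9,0.09577
D13S317,10,0.11609
D13S317,11,0.10147
D13S317,12,0.22009
D13S317,13,0.24869
D13S317,14,0.12669
D13S317,15,0.04001
D7S820,10,0.04598
D7S820,11,0.16167
D7S820,12,0.25863
D7S820,13,0.09387
D7S820,14,0.23951
D7S820,15,0.07499
D7S820,16,0.08836
D7S820,17,0.03699
SE33,10,0.04124
SE33,11,0.20511
SE33,12,0.10894
SE33,13,0.13703
SE33,14,0.19966
SE33,15,0.12614
SE33,16,0.1035
SE33,17,0.07838
D10S1248,10,0.01898
D10S1248,11,0.21818
D10S1248,12,0.05981
D10S1248,13,0.17327
D10S1248,14,0.30353
D10S1248,15,0.1057
D10S1248,16,0.0496
D10S1248,17,0.07093
D1S1656,6,0.04286
D1S1656,7,0.11033
D1S1656,8,0.11101
D1S1656,9,0.16701
D1S1656,10,0.25574
D1S1656,11,0.12523
D1S1656,12,0.06934
D1S1656,13,0.11848
D12S391,7,0.0772
D12S391,8,0.21583
D12S391,9,0.09326
D12S391,10,0.16924
D12S391,11,0.05292
D12S391,12,0.19898
D12S391,13,0.12972
D12S391,14,0.06285
D2S1338,8,0.06615
D2S1338,9,0.03032
D2S1338,10,0.07295
D2S1338,11,0.17605
D2S1338,12,0.21218
D2S1338,13,0.17157
D2S1338,14,0.14442
D2S1338,15,0.12636
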