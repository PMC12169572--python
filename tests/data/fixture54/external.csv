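country_id,value
SYN01,5.402453819
SYN02,27.01793687
SYN03,21.38551013
SYN04,15.70303933
SYN05,5.893181578
SYN06,14.48783334
SYN07,39.52834413
SYN08,34.98915645
SYN09,18.57461855
SYN10,19.82333175
SYN11,35.0626183
SYN12,27.35211365
SYN13,21.5872064
SYN14,24.10197812
SYN15,25.57623067
SYN16,31.39046517
SYN17,37.1037378
SYN18,28.48070257
SYN19,5.124520263
SYN20,7.032706541
SYN21,32.43910382
SYN22,16.67038943
SYN23,6.691695018
SYN24,34.90309154
SYN25,32.48864615
SYN26,28.25542204
SYN27,23.52533919
SYN28,25.7556464
SYN29,28.95328705
SYN30,38.43300857
SYN31,11.70196167
SYN32,6.83685385
SYN33,19.59957761
SYN34,30.22578687
SYN35,21.7360585
SYN36,31.23304173
SYN37,6.392955152
SYN38,33.3884634
SYN39,29.83039805
SYN40,20.40307305
SYN41,26.84820408
SYN42,36.61799129
SYN43,15.81778867
SYN44,7.556713619
SYN45,28.31602975
SYN46,28.11425547
SYN47,20.34634351
SYN48,17.06497486
SYN49,13.4669919
SYN50,35.62778688
SYN51,29.94761682
SYN52,24.18458862
SYN53,14.13382691
SYN54,28.03936323
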