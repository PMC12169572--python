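country_id,name,continent,adversity,latent_risk_insecurity,latent_socioeconomic,latent_vulnerability,injected_outlier
SYN01,Synthetic Country 01,Africa,0.5118216247,0.4156723151,0.6571174943,0.5458535826,False
SYN02,Synthetic Country 02,Americas,0.9504636963,0.6897903726,0.7382892267,0.8734114378,False
SYN03,Synthetic Country 03,Asia,0.1441596127,0.3574798212,0.1779719691,0.2573692655,False
SYN04,Synthetic Country 04,Europe,0.9486494471,0.9224396618,0.6860116347,0.7567450727,False
SYN05,Synthetic Country 05,Oceania,0.311831452,0.4812431453,0.2956229521,0.3369489427,False
SYN06,Synthetic Country 06,Africa,0.423326449,0.4379014301,0.525267074,0.5786087706,False
SYN07,Synthetic Country 07,Americas,0.8277025938,0.6616063323,0.7887598869,0.6397527759,False
SYN08,Synthetic Country 08,Asia,0.4091991364,0.288566944,0.3250413592,0.5829050658,False
SYN09,Synthetic Country 09,Europe,0.5495936877,0.57843185,0.4975871318,0.61220734,False
SYN10,Synthetic Country 10,Oceania,0.02755911324,0.2352641943,0.1455677977,0.1272274572,False
SYN11,Synthetic Country 11,Africa,0.7535131087,0.778129941,0.72695445,0.7199132529,False
SYN12,Synthetic Country 12,Americas,0.5381433132,0.4612636675,0.5134790082,0.490994781,False
SYN13,Synthetic Country 13,Asia,0.3297317165,0.2953776517,0.4067676996,0.3452600813,False
SYN14,Synthetic Country 14,Europe,0.7884287034,0.7436995064,0.8038054735,0.7030409775,False
SYN15,Synthetic Country 15,Oceania,0.3031948293,0.4537528304,0.4301784636,0.217253227,False
SYN16,Synthetic Country 16,Africa,0.4534978895,0.6065497845,0.4269507017,0.4655199906,False
SYN17,Synthetic Country 17,Americas,0.1340416972,0.1389866372,0.2283480809,0.3853087121,False
SYN18,Synthetic Country 18,Asia,0.4031129864,0.426842807,0.3924889614,0.3678186591,False
SYN19,Synthetic Country 19,Europe,0.2034552407,0.4108334271,0.1753390677,0.3668840562,False
SYN20,Synthetic Country 20,Oceania,0.2623133404,0.3104344104,0.2445918015,0.3164560053,False
SYN21,Synthetic Country 21,Africa,0.7503646726,0.7021058895,0.6103972175,0.5880395836,False
SYN22,Synthetic Country 22,Americas,0.280408758,0.2036333338,0.2905262993,0.4677869018,False
SYN23,Synthetic Country 23,Asia,0.4851909744,0.5416716482,0.4335480397,0.3446818675,False
SYN24,Synthetic Country 24,Europe,0.9807371998,0.9622426258,0.8595259547,0.7775687178,False
SYN25,Synthetic Country 25,Oceania,0.9616571937,0.9212076344,0.9646670283,0.9728678003,False
SYN26,Synthetic Country 26,Africa,0.7247899408,0.7730090386,0.739752199,0.5859969974,False
SYN27,Synthetic Country 27,Americas,0.5412268555,0.576965413,0.6161989833,0.6335721554,False
SYN28,Synthetic Country 28,Asia,0.276891204,0.267489523,0.421604393,0.3755287874,False
SYN29,Synthetic Country 29,Europe,0.1606520088,0.3430115058,0.2915527253,0.3542671184,False
SYN30,Synthetic Country 30,Oceania,0.9699254132,0.742450212,0.9542554664,0.8680431159,False
SYN31,Synthetic Country 31,Africa,0.5160685855,0.6106304603,0.5681370565,0.470057067,False
SYN32,Synthetic Country 32,Americas,0.1158656125,0.0999213055,0.231212858,0.3093425641,False
SYN33,Synthetic Country 33,Asia,0.6234897555,0.6840891729,0.4595679714,0.4443881935,False
SYN34,Synthetic Country 34,Europe,0.7766831143,0.59303036,0.6902129482,0.6777220656,False
SYN35,Synthetic Country 35,Oceania,0.6130033011,0.5416464097,0.4929516093,0.5406586817,False
SYN36,Synthetic Country 36,Africa,0.9172977048,0.7371298433,0.6819172826,0.785230595,False
SYN37,Synthetic Country 37,Americas,0.03959287666,0.2351161242,0.1795344904,0.06600121961,False
SYN38,Synthetic Country 38,Asia,0.5285892633,0.4235840477,0.6055380721,0.4367645441,False
SYN39,Synthetic Country 39,Europe,0.4593358829,0.4404119667,0.4100370509,0.490150595,False
SYN40,Synthetic Country 40,Oceania,0.06234957915,0.04539208394,0.2742762334,0.1599754401,False
SYN41,Synthetic Country 41,Africa,0.6413281691,0.5276781322,0.6066185753,0.6864265801,False
SYN42,Synthetic Country 42,Americas,0.8526328385,0.7231996312,0.6415573939,0.7783839637,False
SYN43,Synthetic Country 43,Asia,0.5929410181,0.4468350837,0.7045490359,0.6734387181,False
SYN44,Synthetic Country 44,Europe,0.2600974477,0.3720161972,0.3025590806,0.4017764646,False
SYN45,Synthetic Country 45,Oceania,0.839881521,0.7020443457,0.6764873414,0.768464099,False
SYN46,Synthetic Country 46,Africa,0.5094958815,0.5742352985,0.6107466283,0.4429317977,False
SYN47,Synthetic Country 47,Americas,0.5108888845,0.5537820224,0.3949603189,0.5924503595,False
SYN48,Synthetic Country 48,Asia,0.7530302077,0.65648917,0.7471982837,0.6025014188,False
SYN49,Synthetic Country 49,Europe,0.1479220358,0.3637415767,0.1598928478,0.1261087586,False
SYN50,Synthetic Country 50,Oceania,0.8196267191,0.7633792386,0.6914862362,0.8625980769,False
SYN51,Synthetic Country 51,Africa,0.683286906,0.7213831398,0.5478707977,0.6403041957,False
SYN52,Synthetic Country 52,Americas,0.7870969416,0.6535062763,0.8033362569,0.7831361484,False
SYN53,Synthetic Country 53,Asia,0.191616259,0.2972321682,0.2511537469,0.2928982236,False
SYN54,Synthetic Country 54,Europe,0.8023641611,0.6205439783,0.8540627567,0.7451288319,False
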