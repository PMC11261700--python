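ubcg_001
ubcg_002
ubcg_003
ubcg_004
ubcg_005
ubcg_006
ubcg_007
ubcg_008
ubcg_009
ubcg_010
ubcg_011
ubcg_012
ubcg_013
ubcg_014
ubcg_015
ubcg_016
ubcg_017
ubcg_018
ubcg_019
ubcg_020
ubcg_021
ubcg_022
ubcg_023
ubcg_024
ubcg_025
ubcg_026
ubcg_027
ubcg_028
ubcg_029
ubcg_030
ubcg_031
ubcg_032
ubcg_033
ubcg_034
ubcg_035
ubcg_036
ubcg_037
ubcg_038
ubcg_039
ubcg_040
ubcg_041
ubcg_042
ubcg_043
ubcg_044
ubcg_045
ubcg_046
ubcg_047
ubcg_048
ubcg_049
ubcg_050
ubcg_051
ubcg_052
ubcg_053
ubcg_054
ubcg_055
ubcg_056
ubcg_057
ubcg_058
ubcg_059
ubcg_060
ubcg_061
ubcg_062
ubcg_063
ubcg_064
ubcg_065
ubcg_066
ubcg_067
ubcg_068
ubcg_069
ubcg_070
ubcg_071
ubcg_072
ubcg_073
ubcg_074
ubcg_075
ubcg_076
ubcg_077
ubcg_078
ubcg_079
ubcg_080
ubcg_081
ubcg_082
ubcg_083
ubcg_084
ubcg_085
ubcg_086
ubcg_087
ubcg_088
ubcg_089
ubcg_090
ubcg_091
ubcg_092
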