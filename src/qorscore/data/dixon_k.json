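{
"description": "Dixon up-down k factors by terminal response pattern (X=response/step down, O=no response/step up); probit ML location with spread = one log-step, staircase-implied levels, final trial at 0.",
"k": {
"OOOOOX": -0.377114,
"OOOOX": -0.377122,
"OOOOXO": 0.894003,
"OOOOXX": 0.027921,
"OOOX": -0.37757,
"OOOXO": 0.893873,
"OOOXOO": 0.315244,
"OOOXOX": -0.432426,
"OOOXX": 0.025999,
"OOOXXO": 1.13913,
"OOOXXX": 0.5,
"OOX": -0.388085,
"OOXO": 0.88996,
"OOXOO": 0.314374,
"OOXOOO": -0.153829,
"OOXOOX": -0.86087,
"OOXOX": -0.43898,
"OOXOXO": 0.737335,
"OOXOXX": 0.168652,
"OOXX": 0.0,
"OOXXO": 1.121573,
"OOXXOO": 0.372007,
"OOXXOX": -0.168652,
"OOXXX": 0.448809,
"OOXXXO": 1.5,
"OOXXXX": 0.897162,
"OX": -0.5,
"OXO": 0.841647,
"OXOO": 0.299193,
"OXOOO": -0.157059,
"OXOOOO": -0.547046,
"OXOOOX": -1.250123,
"OXOOX": -0.878427,
"OXOOXO": 0.372007,
"OXOOXX": -0.168652,
"OXOX": -0.5,
"OXOXO": 0.700532,
"OXOXOO": 0.021541,
"OXOXOX": -0.5,
"OXOXX": 0.083538,
"OXOXXO": 1.168652,
"OXOXXX": 0.610788,
"OXX": -0.177961,
"OXXO": 1.0,
"OXXOO": 0.305483,
"OXXOOO": -0.295915,
"OXXOOX": -0.831348,
"OXXOX": -0.305483,
"OXXOXO": 0.831348,
"OXXOXX": 0.295915,
"OXXX": 0.194366,
"OXXXO": 1.288087,
"OXXXOO": 0.5,
"OXXXOX": -0.043148,
"OXXXX": 0.555297,
"OXXXXO": 1.603423,
"OXXXXX": 0.893064,
"XO": 0.5,
"XOO": 0.177961,
"XOOO": -0.194366,
"XOOOO": -0.555297,
"XOOOOO": -0.893064,
"XOOOOX": -1.603423,
"XOOOX": -1.288087,
"XOOOXO": 0.043148,
"XOOOXX": -0.5,
"XOOX": -1.0,
"XOOXO": 0.305483,
"XOOXOO": -0.295915,
"XOOXOX": -0.831348,
"XOOXX": -0.305483,
"XOOXXO": 0.831348,
"XOOXXX": 0.295915,
"XOX": -0.841647,
"XOXO": 0.5,
"XOXOO": -0.083538,
"XOXOOO": -0.610788,
"XOXOOX": -1.168652,
"XOXOX": -0.700532,
"XOXOXO": 0.5,
"XOXOXX": -0.021541,
"XOXX": -0.299193,
"XOXXO": 0.878427,
"XOXXOO": 0.168652,
"XOXXOX": -0.372007,
"XOXXX": 0.157059,
"XOXXXO": 1.250123,
"XOXXXX": 0.547046,
"XXO": 0.388085,
"XXOO": 0.0,
"XXOOO": -0.448809,
"XXOOOO": -0.897162,
"XXOOOX": -1.5,
"XXOOX": -1.121573,
"XXOOXO": 0.168652,
"XXOOXX": -0.372007,
"XXOX": -0.88996,
"XXOXO": 0.43898,
"XXOXOO": -0.168652,
"XXOXOX": -0.737335,
"XXOXX": -0.314374,
"XXOXXO": 0.86087,
"XXOXXX": 0.153829,
"XXXO": 0.37757,
"XXXOO": -0.025999,
"XXXOOO": -0.5,
"XXXOOX": -1.13913,
"XXXOX": -0.893873,
"XXXOXO": 0.432426,
"XXXOXX": -0.315244,
"XXXXO": 0.377122,
"XXXXOO": -0.027921,
"XXXXOX": -0.894003,
"XXXXXO": 0.377114
},
"version": 1
}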