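year	support_ratio
2010	7.4
2011	7.07
2012	6.74
2013	6.41
2014	6.09
2015	5.76
2016	5.43
2017	5.1
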