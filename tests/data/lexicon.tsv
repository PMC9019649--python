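word	relevant	s_rater1	s_rater2	m_rater1	m_rater2
abuse	1	1	1	0	0
suffering	1	1	1	0	0
dementia	1	1	1	1	1
sick	1	2	2	1	1
frail	1	2	2	1	1
shoe	1	3	3	0	0
community	1	3	3	0	0
care	1	3	3	1	1
active	1	4	4	0	0
venerable	1	5	5	0	0
hero	1	5	5	0	0
market	0	3	3	0	0
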