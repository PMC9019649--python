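doc_id	year	source	path
y2010a	2010	fixture	docs/y2010a.txt
y2011a	2011	fixture	docs/y2011a.txt
y2012a	2012	fixture	docs/y2012a.txt
y2013a	2013	fixture	docs/y2013a.txt
y2014a	2014	fixture	docs/y2014a.txt
y2014b	2014	fixture	docs/y2014b.txt
y2015a	2015	fixture	docs/y2015a.txt
y2015b	2015	fixture	docs/y2015b.txt
y2016a	2016	fixture	docs/y2016a.txt
y2016b	2016	fixture	docs/y2016b.txt
y2017a	2017	fixture	docs/y2017a.txt
y2017b	2017	fixture	docs/y2017b.txt
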