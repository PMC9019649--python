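The venerable elderly teacher received care after long service years. Students remembered patient lessons delivered inside bright classrooms. Rain tapped gently against tall library windows throughout quiet afternoons. Clerks stacked heavy ledgers beside wooden counters every evening. Lanterns glowed softly above cobbled streets tonight.
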