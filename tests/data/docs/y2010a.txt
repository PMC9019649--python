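The elderly hero walked across town square every morning. Neighbours greeted old friends warmly near stone fountain. Children listened eagerly whenever long stories began flowing under evening sky. Gardens bloomed quietly behind narrow lanes during warm afternoons. Vendors arranged fresh fruit baskets along busy pavements yesterday.
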