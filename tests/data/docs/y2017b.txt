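Stormy weather delayed evening ferry departures repeatedly. Dockhands secured straining mooring ropes against rising swells. Meteorologists tracked shifting pressure systems overnight. Shopkeepers lowered rattling aluminium shutters early. Streetlamps flickered weakly along flooded junctions afterwards.
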