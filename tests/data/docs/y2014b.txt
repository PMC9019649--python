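Festival drummers rehearsed complicated rhythms inside echoing pavilions. Tailors measured silk fabric beneath flickering shop lights. Cyclists pedalled slowly along winding coastal roads. Librarians shelved returned novels before closing hour. Painters touched weathered shutters using bright enamel colours.
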