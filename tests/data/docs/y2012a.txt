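Many residents admired the active elderly swimmer crossing cold waters. Morning joggers circled misty reservoir paths before sunrise. Coaches timed practice laps using worn stopwatches daily. Ferries carried commuters across calm harbour channels smoothly. Seagulls wheeled loudly above crowded jetties afterwards.
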