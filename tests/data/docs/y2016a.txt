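Nurses monitored the elderly resident with dementia overnight. Pharmacists counted tablets behind glass partitions quietly. Visitors signed thick registers near guarded entrances. Cleaners mopped long corridors beneath buzzing fluorescent lights.
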