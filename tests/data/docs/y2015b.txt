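Monsoon clouds gathered darkly above container terminals. Crane operators loaded stacked cargo onto waiting vessels. Engineers inspected rusted pipeline joints near refinery gates. Traders haggled loudly over wholesale vegetable prices. Taxis queued patiently outside glittering hotel lobbies.
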