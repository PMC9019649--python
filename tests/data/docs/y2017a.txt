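The frail elderly widow kept suffering silently. Relatives telephoned distant cousins seeking practical advice. Charities delivered cooked meals across humid neighbourhoods weekly. Journalists profiled overworked caregivers facing mounting bills.
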