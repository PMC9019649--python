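The elderly shopper visited community hall wearing a shoe. Stalls displayed woven rattan crafts beside painted doorways. Volunteers folded donated clothing into labelled cartons carefully. Buses idled outside covered walkways during heavy rain. Hawkers ladled steaming noodle broth into ceramic bowls nightly.
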