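An elderly sick man endured abuse while frail limbs trembled. Social workers documented troubling household visits thoroughly. Counsellors arranged urgent follow-up meetings downtown. Reporters questioned officials about shelter capacity limits.
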